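# Methods

## Coordinates, frames and the genetic code

All nucleotide intervals are 0-based, half-open, on the forward strand.
Amino-acid positions inside domain motifs are 1-based columns of the seed
alignment, so "position 14" is the 14th reference column. Frames follow
the GenBank convention: +1/+2/+3 read the forward strand at codon offsets
0/1/2, −1/−2/−3 read the reverse complement at offsets 0/1/2. Translation
uses the standard genetic code only; codons containing N translate to X
(keeping frame lengths deterministic), stops render as `*`. Report output
(TSV) uses 1-based inclusive coordinates nowhere — tables carry the
internal 0-based half-open values; this convention is stated in the
column headers' documentation rather than converted, to keep files
round-trippable.

## Profile HMM

`build_profile` turns a seed alignment into a profile HMM: columns whose
non-gap fraction is ≥ `match_threshold` (default 0.5, with ≥ comparison)
become match states. Emissions and transitions are smoothed with a
single-parameter background-mixing pseudocount,
`p = (count + τ·prior)/(total + τ)` with τ = 1 by default; the prior is
the background distribution (uniform 1/20) for emissions and uniform over
the outgoing bundle for transitions. Insert states emit the background,
so insertions cost only their transitions. Sequence weighting is uniform
— a deliberate simplification appropriate for small curated seeds, and a
known limitation for large redundant alignments. Delete→insert residues
in a seed row have no edge in this topology and are ignored for
transition counting.

Search is uni-local: uniform entry into any of the n match states
(probability 1/n) and uniform exit from any match state (1/n), with the
unaligned sequence flanks scored under the null, so scores are log₂-odds
(bits) of the aligned core. `forward_score` sums over all local paths;
`viterbi_score` maximizes and reports the half-open peptide interval with
deterministic tie-breaks (earliest start, then shortest interval). Both
recursions are checked in the test suite against an exhaustive
enumeration of every path on small models, to 1e-9 bits.

Peptides are split at stop codons and each stop-free segment scored
separately: a domain may not cross a stop, which is what lets a
stop-interrupted duplicate domain be detected downstream of the stop and
then characterized by `stop_codon_downstream`.

The reporting floor is a bit score, not an e-value: reproducing
HMMER-style Gumbel calibration is out of scope, and a fixed floor keeps
the search deterministic. The default (15 bits) was calibrated once on a
seeded random-sequence null — 10⁵ random residues yield zero hits at this
floor (the test suite pins this), while planted domains down to 60 %
identity score ≈ 30 bits and the seed consensus ≈ 113 bits, leaving wide
margins on both sides. The floor is exposed as `--hmm-report-bits`.

## Smith–Waterman detector

`sw_align` is an affine-gap Gotoh local alignment with BLOSUM62 and the
BLAST gap convention (a gap of length k costs 11 + k). Traceback
tie-breaks are fixed: the end cell is the earliest (query, target) index
pair among maxima, and moves prefer diagonal, then up, then left. The raw
score replaces the database e-value of a BLAST search; the default floor
(60) was likewise calibrated once against the random null (null maxima
≈ 35, planted 60 %-identity domains ≥ 114). A second, exhaustive
dynamic program and Biopython's `PairwiseAligner` serve as independent
cross-checks in the tests.

## Envelope extension and hit merging

A local alignment trims mismatching domain termini. Both detectors
therefore extend their envelope to the full seed span — by the unaligned
consensus flanks (SW) or by the unused entry/exit match states (HMM) —
clamped to the stop-free segment. On substitution-only divergence this
recovers the exact planted boundaries, which is what makes the
inter-domain distances in the end-to-end test exact rather than
approximate. Overlapping hits per (contig, domain, strand) are collapsed
to the best-scoring one (ties leftmost); with both detectors enabled the
extended envelopes coincide, so collapsing keeps one representative per
locus. Within one stop-free segment the scan recurses on the flanks of
each accepted hit, so tandem copies in a single ORF are all found.

## Linking and distances

For each contig and strand with both domains, the primary pair minimizes
the non-negative gap `od2.nt_start − od1.nt_end` (mirrored on −). Pairs
with the domains in different frames are kept but flagged
`same_frame=False`; only same-frame pairs count as high-confidence. This
preserves both the strict both-domains-one-frame definition and the
observed tandem OD2 duplicates that sit in a shifted frame. Additional
OD2 hits downstream of the primary OD2 become supplementary pairs flagged
`tandem_duplicate`. The distance summary takes one value per contig (the
primary pair), excludes tandem and cross-frame pairs and optionally
alternate-isoform contigs, and reports sample SD (n−1) by default with a
population-SD switch, since either convention is defensible for a survey
statistic.

## OD1 classification

Hit peptides are mapped onto seed columns through the SW traceback
against the seed consensus, with unaligned flanks projected
column-for-column; alignments not covering columns 1–21 are
UNCLASSIFIED/"incomplete". "-like" tetrads are operationalized as a
BLOSUM62 score against the prototype (TPPN for type A, RTPK for type B)
of at least `similarity_floor` (default 0.5) of the prototype self-score;
the position-14 anchor is exact (K for type A, I for type B with ≥ 2/3 of
Ile-Ser-Cys matching at 14–16). Rules are checked A-then-B and are
mutually exclusive by their anchors. The zinc-finger topology reads the
residues at the eight coordinating columns — by default the seed-consensus
Cys/His columns (6, 9, 11, 17, 24, 27, 30, 33 on the shipped seed),
configurable because the canonical coordinating set is a property of the
chosen reference alignment — and run-length encodes the C/H reading;
substituted residues drop out (a lost cysteine reads C2H2C3), gaps
surface as `?`. Extra Cys/His outside the coordinating columns are
counted and reported as a note, not folded into the topology string,
since their effect on zinc coordination cannot be resolved from sequence
alone.

## Evidence and paralogy

Categories in order of strength: LINKED (≥ 1 same-frame pair), SINGLETONS
(a type-A OD1 and/or an OD2 on singleton contigs), TYPE_B_ONLY (type-B
OD1 evidence only, no OD2 — weak evidence, as type-B motifs may derive
from another DMRT-family gene), ABSENT. The category is a deterministic,
order-independent function of the hit multiset. Paralogy needs either two
high-confidence contigs whose OD2 peptides fall below 0.90 amino-acid
identity (identities over the SW-aligned span), or one high-confidence
contig plus a divergent OD2 singleton; 0.90 is a conservative default and
configurable, as the underlying divergence cut-off is a judgment call.

## Splice-isoform detection

The junction is the most C-terminal conserved glutamate of the OD2
reference (its final column on the shipped seed). Read matching is
deliberately exact-with-budget in peptide space rather than probabilistic
alignment: a read anchors if one of its six frames matches the anchor
suffix over ≥ 8 aa with ≤ 1 mismatch — parameters matched to short-read
anchor lengths; both are configurable. Reads anchored but ending at or
before the junction are counted as uninformative. Tails are keyed on
their first 5 aa (shorter tails join a cluster they prefix unambiguously);
clusters under 2 reads go to the unassigned pool, and ≥ 2 surviving
clusters call an alternative isoform. The 5-aa/2-read defaults are the
package's own operating point, justified by the seeded operating-
characteristics test (100 % calls on two-isoform replicates, 0 % false
calls on single-isoform replicates, 50 replicates each). Reads matching
the anchor in more than one frame are flagged (`nt_consistent=False`) but
kept — a guard against convergent peptide tails from different frames.
Sex-specificity is never inferred; clusters are labelled only
reference/alternative.

## Synthetic data generator

The generator is the package's study condition, not a tuning knob. The
default configuration plants twelve taxa: eight LINKED (inter-domain gaps
84–1725 nt, including a reverse-strand gene, modified zinc fingers
C2H2CHC2 / C2H3C3 / C2H2C3, a tandem OD2 duplicate 31 nt downstream in a
shifted frame, and the two paralogy flavours at OD2 identities 0.63 and
0.70), two SINGLETONS (a fragmented "genomic" pair of contigs with
≈ 3.1 kb of intervening sequence, and an OD1-only transcript with its
first in-frame stop exactly 423 nt downstream), one TYPE_B_ONLY and one
ABSENT taxon, plus a two-isoform read set (tails VSQDE / GKRSL, 30 reads
per isoform, 100 nt reads, 0.5 % substitution error) anchored at the OD2
junction. In-frame gaps are multiples of 3 by construction — a same-frame
pair cannot have a gap ≢ 0 (mod 3), so the 1,724-nt reconstruction is
planted as a cross-frame pair, which the linker measures and flags.

Domain prototypes are a small constructed seed alignment shipped with the
package (six rows each for OD1 and OD2), synthetic stand-ins exhibiting
exactly the features the rules need: the TPPN tetrad, Lys14/Lys21, eight
Cys/His coordinating columns, and the OD2 Leu-Leu-Val block with the
terminal glutamate. Real seed alignments drop in via configuration.
Divergence is planted by `mutate_to_identity`: exactly
`round((1−target)·len)` positions substituted with BLOSUM62-plausible
(score ≥ 0) non-Cys/His replacements, avoiding the diagnostic and
terminal positions so planted copies stay classifiable and their
envelopes exactly recoverable. Reads carry substitution errors only;
indels would shift frames and confound the peptide-space detector, so an
indel mode is intentionally absent from the defaults.

What the generator does *not* emulate — assembly chimerism, indel
sequencing error, expression-level variation, UTR splice structure,
base-composition bias beyond a GC knob — bounds what green tests show:
they demonstrate the pipeline's correctness on clean planted signal and
its specificity on i.i.d. random sequence, not robustness to real
assembler artifacts.

## Problem sizes and determinism

The default dataset is 15 contigs (~0.6–6.5 kb) and 80 reads; a full
scan-classify-aggregate pass takes ~10 s on one CPU, and the acceptance
script (which regenerates everything, runs both oracles, a 2×10⁴-residue
null and 100 isoform replicates) ~20 s. All randomness flows from a
single integer seed through `numpy.random.default_rng`; identical seeds
give byte-identical FASTA/FASTQ/TSV/JSON outputs, and every output table
carries the package version and a config digest in its header.

## Known limitations

No e-value statistics (bit-score floors calibrated on a synthetic null
instead); no DNA-level or translated-vs-translated search; no spliced
alignment or transcript assembly; uniform sequence weights in profile
construction; the OD1 column coordinate system is only as good as the
configured seed alignment; paralogy and isoform calls are sequence-level
hypotheses, not confirmed gene models.
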