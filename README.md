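# dsxscan

Discovery and characterization of insect *doublesex* (*dsx*) orthologs
from transcriptome and genome contigs.

*doublesex* is the terminal "double-switch" of the insect
sex-determination cascade. Its protein carries two diagnostic domains:
the DM DNA-binding zinc-finger domain (here **OD1**, with a canonical
C2H2C4 Cys-His coordination pattern) and the *doublesex*-specific
dimerization domain (**OD2**). A transcript contig encoding both domains,
with OD2 downstream of OD1 in the same reading frame, is the strongest
("high-confidence") evidence that a taxon expresses *dsx*. dsxscan is a
pipeline for running that survey: it finds the domains, types the motifs,
aggregates per-taxon evidence, flags putative paralogy, measures the
inter-domain distance heterogeneity, and detects alternative splice
isoforms from raw short reads — all testable end-to-end on synthetic data
with a ground-truth manifest, no downloads required.

## What it computes

- **Domain search** — each contig is translated in all six frames and
  searched with two detectors: affine-gap Smith–Waterman against the seed
  consensus (BLOSUM62, gap open 11 / extend 1), and a from-scratch
  uni-local profile HMM built from the seed alignment (match emissions
  `(counts + τ·background)/(total + τ)`; forward and Viterbi scoring in
  bits, i.e. log₂ odds against an i.i.d. background null).
- **Linking** — OD1 hits are paired with downstream OD2 hits on the same
  contig and strand; same-frame pairs are high-confidence, extra OD2 hits
  downstream are flagged tandem duplicates.
- **OD1 classification** — type A (Thr-Pro-Pro-Asn-like positions 1–4,
  Lys at alignment position 14) versus type B (Arg-Thr-Pro-Lys-like 1–4,
  Ile-Ser-Cys from position 14); the position-21 lysine (DNA salt bridge)
  is flagged independently; the Cys/His residues at the eight
  zinc-coordinating columns are run-length encoded (C2H2C4, C2H2CHC2,
  C2H3C3, C2H2C3, ...).
- **Evidence aggregation** — each taxon is LINKED, SINGLETONS,
  TYPE_B_ONLY or ABSENT; paralogy is called from two high-confidence
  contigs with OD2 amino-acid identity < 0.90, or one high-confidence
  contig plus a divergent OD2 singleton.
- **Distances** — the nucleotide gap between the OD1 3′ end and the OD2
  5′ start per high-confidence transcript, with mean ± SD and labelled
  extremes.
- **Splice isoforms** — reads are six-frame translated, anchored to the
  OD2 suffix ending at the conserved 3′ glutamate (≥ 8 aa overlap, ≤ 1
  mismatch), and their post-junction 5-aa tails clustered; ≥ 2 supported
  clusters call an alternative isoform.

## Worked example

The `analysis/` scripts run the whole survey on the default synthetic
dataset (12 taxa covering every evidence class):

```
python analysis/01_simulate.py
python analysis/02_scan_domains.py
python analysis/03_classify_motifs.py
python analysis/04_aggregate_evidence.py
python analysis/05_detect_isoforms.py
```

`02_scan_domains.py` reports:

```
15 contigs -> 12 OD1 hits, 12 OD2 hits
9 high-confidence (same-frame) pairs; 1 tandem OD2 duplicates; 1 cross-frame pairs
  ...
  Phasmatodea_sp01_c01: inter-domain gap 84 nt on +
```

i.e. every planted domain is recovered at its exact coordinates, and the
phasmid-like taxon shows the smallest inter-domain gap (84 nt).
`04_aggregate_evidence.py` then prints the per-taxon evidence matrix —
8 LINKED, 2 SINGLETONS, 1 TYPE_B_ONLY, 1 ABSENT, with the two planted
paralogy cases flagged (`TWO_HC` and `HC_PLUS_DIVERGENT_OD2`) — and the
distance summary:

```
inter-domain distance over 9 high-confidence transcripts: 416 +/- 500 nt (sample SD)
smallest: 84 nt (Phasmatodea_sp01); largest: 1725 nt (Hymenoptera_sp12); ...
```

and `05_detect_isoforms.py` calls the planted alternative isoform:

```
anchor Archaeognatha_sp09_c01, junction at OD2 column 32 (the conserved glutamate)
  cluster 1: tail VSQDE, 28 reads (reference)
  cluster 2: tail GKRSL, 26 reads
alternative isoform CALLED
```

The same stages are available as a CLI
(`dsxscan simulate|scan|classify|report|splice`); run `dsxscan --help`.

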