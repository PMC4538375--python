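"""Detect alternative splice isoforms from short reads anchored at the 3' OD2.

In holometabolous insects the sex-specific exon of *doublesex* begins
immediately downstream of a conserved glutamic-acid residue at the 3' end
of the dimerization (OD2) domain.  This module reproduces that read-level
analysis: reads are six-frame translated, pattern-matched to the OD2
suffix ending at the junction glutamate, and their downstream peptide
tails clustered; two or more well-supported distinct tails constitute an
alternative-isoform call.

Matching is exact-with-budget in peptide space: a read anchors when one of
its frames matches the anchor suffix over at least ``min_overlap_aa``
residues with at most ``max_mismatch`` mismatches.  A nucleotide-space
consistency check flags (but keeps) anchored reads whose nucleotide
junction does not fall on the anchored frame's codon boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import SequenceRecord, six_frame_translate

DEFAULT_MIN_OVERLAP_AA = 8
DEFAULT_MAX_MISMATCH = 1
DEFAULT_TAIL_LEN_AA = 5
DEFAULT_MIN_CLUSTER_READS = 2


class SpliceError(ValueError):
    pass


@dataclass
class AnchoredRead:
    read_id: str
    frame: int
    overlap_aa: int
    mismatches: int
    tail: str  # peptide downstream of the junction (may be empty)
    nt_consistent: bool = True

    @property
    def informative(self) -> bool:
        return len(self.tail) >= 1


@dataclass
class TailCluster:
    consensus: str
    read_ids: list[str]

    @property
    def count(self) -> int:
        return len(self.read_ids)


@dataclass
class IsoformCall:
    anchor_id: str
    junction_aa: int
    clusters: list[TailCluster]
    unassigned: list[str]
    reference_tail: int | None  # index into clusters, or None
    alternative_called: bool
    n_informative: int


def locate_junction(od2_reference: str) -> int:
    """1-based column of the most C-terminal conserved glutamate in the OD2 reference.

    Divergence between isoforms is assessed starting at the next column.
    """
    clean = od2_reference.replace("-", "").replace(".", "")
    pos = clean.rfind("E")
    if pos < 0:
        raise SpliceError(
            "no glutamic-acid residue in the OD2 reference 3' region; "
            "configure the junction column manually"
        )
    return pos + 1


def _best_anchor(peptide: str, anchor: str, min_overlap: int, max_mismatch: int):
    """Best placement of the anchor suffix ending inside ``peptide``.

    Returns (junction_offset_in_peptide, overlap, mismatches) or None.
    Preference: fewest mismatches, then longest overlap, then earliest
    junction position.
    """
    best = None
    for p in range(min_overlap, len(peptide) + 1):
        ov = min(len(anchor), p)
        if ov < min_overlap:
            continue
        mism = sum(1 for a, b in zip(peptide[p - ov : p], anchor[len(anchor) - ov :]) if a != b)
        if mism > max_mismatch:
            continue
        cand = (mism, -ov, p)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    mism, neg_ov, p = best
    return p, -neg_ov, mism


def anchor_reads(
    reads: list[SequenceRecord],
    anchor_prefix: str,
    min_overlap_aa: int = DEFAULT_MIN_OVERLAP_AA,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> list[AnchoredRead]:
    """Anchor reads to the OD2 suffix ending at the junction.

    ``anchor_prefix`` is the reference peptide ending exactly at the
    junction residue.  Unanchored reads are simply absent from the result.
    """
    if not anchor_prefix:
        raise SpliceError("empty anchor prefix")
    anchored: list[AnchoredRead] = []
    for read in reads:
        if len(read.residues) < 3:
            continue
        best: tuple | None = None
        n_frames_anchoring = 0
        for fr in six_frame_translate(read):
            frame_hit = False
            for seg_off, seg in _stop_free(fr.peptide):
                hit = _best_anchor(seg, anchor_prefix, min_overlap_aa, max_mismatch)
                if hit is None:
                    continue
                frame_hit = True
                p, ov, mism = hit
                tail = seg[p:]
                cand = (mism, -ov, fr.frame, seg_off + p)
                if best is None or cand < best[:4]:
                    best = (mism, -ov, fr.frame, seg_off + p, tail)
            if frame_hit:
                n_frames_anchoring += 1
        if best is not None:
            mism, neg_ov, frame, junction_pos, tail = best
            # a read matching the anchor in more than one frame is suspect
            # (convergent peptide tails from different frames) - flagged, kept
            anchored.append(
                AnchoredRead(
                    read.id, frame, -neg_ov, mism, tail,
                    nt_consistent=(n_frames_anchoring == 1),
                )
            )
    return anchored


def _stop_free(peptide: str):
    pos = 0
    for seg in peptide.split("*"):
        if seg:
            yield pos, seg
        pos += len(seg) + 1


def cluster_tails(
    anchored: list[AnchoredRead],
    anchor_id: str,
    junction_aa: int,
    reference_tail: str | None = None,
    tail_len_aa: int = DEFAULT_TAIL_LEN_AA,
    min_cluster_reads: int = DEFAULT_MIN_CLUSTER_READS,
) -> IsoformCall:
    """Group divergence-informative reads by their post-junction tail.

    Reads are keyed on the first ``tail_len_aa`` tail residues; shorter
    observed tails join a cluster whose key they prefix unambiguously.
    Clusters under ``min_cluster_reads`` go to the unassigned pool.  An
    alternative isoform is called when two or more clusters survive.
    """
    informative = sorted(
        (r for r in anchored if r.informative), key=lambda r: r.read_id
    )
    full: dict[str, list[str]] = {}
    short: list[AnchoredRead] = []
    for r in informative:
        if len(r.tail) >= tail_len_aa:
            full.setdefault(r.tail[:tail_len_aa], []).append(r.read_id)
        else:
            short.append(r)
    unassigned: list[str] = []
    for r in short:
        matches = [k for k in full if k.startswith(r.tail)]
        if len(matches) == 1:
            full[matches[0]].append(r.read_id)
        else:
            unassigned.append(r.read_id)

    clusters = []
    for key in sorted(full, key=lambda k: (-len(full[k]), k)):
        ids = sorted(full[key])
        if len(ids) >= min_cluster_reads:
            clusters.append(TailCluster(consensus=key, read_ids=ids))
        else:
            unassigned.extend(ids)

    ref_idx = None
    if reference_tail is not None:
        ref_key = reference_tail[:tail_len_aa]
        for i, c in enumerate(clusters):
            if c.consensus == ref_key or ref_key.startswith(c.consensus):
                ref_idx = i
                break
    return IsoformCall(
        anchor_id=anchor_id,
        junction_aa=junction_aa,
        clusters=clusters,
        unassigned=sorted(unassigned),
        reference_tail=ref_idx,
        alternative_called=len(clusters) >= 2,
        n_informative=len(informative),
    )


def count_domain_support(
    reads: list[SequenceRecord],
    domain_region: str,
    min_overlap_aa: int = DEFAULT_MIN_OVERLAP_AA,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> int:
    """Number of reads matching anywhere inside a domain peptide region.

    Uses the same exact-with-budget matching rule as :func:`anchor_reads`;
    the counts support relative-expression contrasts between gene copies.
    """
    if len(domain_region) < min_overlap_aa:
        raise SpliceError("domain region shorter than the minimum overlap")
    n = 0
    for read in reads:
        if len(read.residues) < 3:
            continue
        if any(
            _matches_region(seg, domain_region, min_overlap_aa, max_mismatch)
            for fr in six_frame_translate(read)
            for _, seg in _stop_free(fr.peptide)
        ):
            n += 1
    return n


def _matches_region(peptide: str, region: str, min_overlap: int, max_mismatch: int) -> bool:
    # ungapped sliding comparison of the read peptide against the region
    for shift in range(-(len(peptide) - min_overlap), len(region) - min_overlap + 1):
        a = max(0, -shift)
        b = min(len(peptide), len(region) - shift)
        if b - a < min_overlap:
            continue
        mism = 0
        ok = True
        for i in range(a, b):
            if peptide[i] != region[i + shift]:
                mism += 1
                if mism > max_mismatch:
                    ok = False
                    break
        if ok:
            return True
    return False
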