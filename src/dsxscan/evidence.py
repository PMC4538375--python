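"""Aggregate domain evidence per taxon and summarize inter-domain distances.

Evidence categories, strongest first:

* ``LINKED`` — at least one contig carries OD1 and OD2 in the same reading
  frame (a high-confidence transcript);
* ``SINGLETONS`` — no linked contig, but a type-A OD1 and/or an OD2 domain
  occurs on singleton contigs;
* ``TYPE_B_ONLY`` — the only OD1 evidence is type-B and no OD2 exists
  anywhere (weak evidence: type-B singletons may derive from another
  DMRT-family gene);
* ``ABSENT`` — no domain evidence at all.

Paralogy is flagged from either two high-confidence contigs whose OD2
peptides have diverged below an identity threshold, or one high-confidence
contig plus a divergent OD2-bearing singleton.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .domain_scan import DomainHit, LinkedPair, sw_align_full
from .motif_classify import OD1Classification

DEFAULT_IDENTITY_THRESHOLD = 0.90

CATEGORIES = ("LINKED", "SINGLETONS", "TYPE_B_ONLY", "ABSENT")


class EvidenceError(ValueError):
    pass


@dataclass
class TaxonEvidence:
    taxon: str
    order_name: str
    category: str
    n_hc_contigs: int
    n_od1_singletons: int
    n_od2_singletons: int
    paralogy: bool
    paralogy_basis: str  # TWO_HC | HC_PLUS_DIVERGENT_OD2 | NONE
    distances: list[int] = field(default_factory=list)


@dataclass
class DistanceSummary:
    n: int
    mean: float
    sd: float
    min: tuple[str, int]
    max_distance: tuple[str, int]
    max_fragment: tuple[str, int]


def aa_identity(a: str, b: str) -> float:
    """Fraction of identical residues over the local alignment of two peptides.

    Computed from the Smith-Waterman traceback: identities / aligned
    columns (gap columns included via the interval spans).
    """
    if not a or not b:
        return 0.0
    score, (qs, qe), (ts, te), pairs = sw_align_full(a, b)
    if score <= 0 or not pairs:
        return 0.0
    ident = sum(1 for qi, ti in pairs if a[qi] == b[ti])
    span = max(qe - qs, te - ts)
    return ident / span


def categorize_taxon(
    pairs: list[LinkedPair],
    lone_hits: list[DomainHit],
    classifications: dict[str, OD1Classification],
    taxon: str,
    order_name: str = "",
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> TaxonEvidence:
    """Aggregate one taxon's pairs, singleton hits and OD1 classifications.

    ``classifications`` maps a hit key (``contig_id:nt_start``) or bare
    contig id to the OD1 classification of the corresponding hit.
    """
    for p in pairs:
        for h in (p.od1, p.od2):
            if h.taxon is not None and h.taxon != taxon:
                raise EvidenceError(f"hit taxon {h.taxon!r} != {taxon!r}")
    for h in lone_hits:
        if h.taxon is not None and h.taxon != taxon:
            raise EvidenceError(f"hit taxon {h.taxon!r} != {taxon!r}")

    hc = [p for p in pairs if p.same_frame and not p.tandem_duplicate]
    hc_contigs = sorted({p.contig_id for p in hc})
    od1_singles = [h for h in lone_hits if h.domain == "OD1"]
    od2_singles = [h for h in lone_hits if h.domain == "OD2"]

    def cls_of(h: DomainHit) -> OD1Classification | None:
        return classifications.get(f"{h.contig_id}:{h.nt_start}") or classifications.get(
            h.contig_id
        )

    type_a_singles = [
        h for h in od1_singles if (c := cls_of(h)) is not None and c.motif_type == "A"
    ]
    type_b_singles = [
        h for h in od1_singles if (c := cls_of(h)) is not None and c.motif_type == "B"
    ]

    if hc_contigs:
        category = "LINKED"
    elif type_a_singles or od2_singles:
        category = "SINGLETONS"
    elif type_b_singles:
        category = "TYPE_B_ONLY"
    else:
        category = "ABSENT"

    paralogy, basis = detect_paralogy(pairs, od2_singles, identity_threshold)
    distances = sorted(p.interdomain_nt for p in hc) if category == "LINKED" else []
    return TaxonEvidence(
        taxon=taxon,
        order_name=order_name,
        category=category,
        n_hc_contigs=len(hc_contigs),
        n_od1_singletons=len(od1_singles),
        n_od2_singletons=len(od2_singles),
        paralogy=paralogy,
        paralogy_basis=basis,
        distances=distances,
    )


def detect_paralogy(
    pairs: list[LinkedPair],
    od2_singletons: list[DomainHit] = (),
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> tuple[bool, str]:
    """Putative gene duplication from one taxon's evidence.

    TWO_HC: two high-confidence contigs whose OD2 peptides are less than
    ``identity_threshold`` identical.  HC_PLUS_DIVERGENT_OD2: one
    high-confidence contig plus an OD2 singleton below the threshold
    against the high-confidence OD2.
    """
    hc = [p for p in pairs if p.same_frame and not p.tandem_duplicate]
    hc_by_contig: dict[str, LinkedPair] = {}
    for p in hc:
        hc_by_contig.setdefault(p.contig_id, p)
    hc_list = sorted(hc_by_contig.values(), key=lambda p: p.contig_id)
    for i in range(len(hc_list)):
        for j in range(i + 1, len(hc_list)):
            ident = aa_identity(hc_list[i].od2.matched_peptide, hc_list[j].od2.matched_peptide)
            if ident < identity_threshold:
                return True, "TWO_HC"
    for p in hc_list:
        for s in od2_singletons:
            if s.contig_id == p.contig_id:
                continue
            ident = aa_identity(p.od2.matched_peptide, s.matched_peptide)
            if ident < identity_threshold:
                return True, "HC_PLUS_DIVERGENT_OD2"
    return False, "NONE"


def distance_summary(
    all_pairs: list[LinkedPair],
    contig_lengths: dict[str, int] | None = None,
    taxa: dict[str, str] | None = None,
    exclude_alternate_isoforms: bool = True,
    alternate_isoform_contigs: set[str] | None = None,
    population_sd: bool = False,
) -> DistanceSummary:
    """Mean and SD of inter-domain distances over high-confidence pairs.

    One value per contig (the primary pair only; tandem-duplicate pairs are
    excluded), optionally excluding contigs flagged as alternate isoforms.
    Sample SD (n-1) by default; ``population_sd=True`` divides by n.
    """
    alternate_isoform_contigs = alternate_isoform_contigs or set()
    taxa = taxa or {}
    contig_lengths = contig_lengths or {}

    chosen: dict[str, int] = {}
    for p in all_pairs:
        if not p.same_frame or p.tandem_duplicate:
            continue
        if exclude_alternate_isoforms and p.contig_id in alternate_isoform_contigs:
            continue
        if p.contig_id not in chosen:
            chosen[p.contig_id] = p.interdomain_nt
    if not chosen:
        raise EvidenceError("no same-frame linked pairs to summarize")

    values = list(chosen.values())
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        sd = 0.0
    else:
        ss = sum((v - mean) ** 2 for v in values)
        sd = math.sqrt(ss / (n if population_sd else n - 1))

    def label(contig: str) -> str:
        return taxa.get(contig, contig)

    min_contig = min(chosen, key=lambda c: (chosen[c], c))
    max_contig = max(chosen, key=lambda c: (chosen[c], c))
    if contig_lengths:
        frag_contig = max(
            (c for c in chosen if c in contig_lengths),
            key=lambda c: (contig_lengths[c], c),
            default=max_contig,
        )
        frag = (label(frag_contig), contig_lengths.get(frag_contig, 0))
    else:
        frag = (label(max_contig), 0)
    return DistanceSummary(
        n=n,
        mean=mean,
        sd=sd,
        min=(label(min_contig), chosen[min_contig]),
        max_distance=(label(max_contig), chosen[max_contig]),
        max_fragment=frag,
    )
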