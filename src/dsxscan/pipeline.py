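"""End-to-end orchestration: scan -> classify -> aggregate -> splice.

The in-memory entry points (:func:`analyze`, :func:`detect_isoforms`) are
what the tests and the acceptance script drive; the file-based wrappers
(:func:`run_scan`, :func:`run_report`, :func:`run_splice`) implement the
CLI stages, each reading and writing plain TSV/JSON so stages are
independently inspectable and re-runnable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .domain_scan import (
    DEFAULT_HMM_REPORT_BITS,
    DEFAULT_SW_MIN_SCORE,
    DomainHit,
    DomainSeeds,
    LinkedPair,
    link_domains,
    scan_contigs,
)
from .evidence import (
    DEFAULT_IDENTITY_THRESHOLD,
    DistanceSummary,
    TaxonEvidence,
    categorize_taxon,
    distance_summary,
)
from .motif_classify import (
    DEFAULT_SIMILARITY_FLOOR,
    OD1Classification,
    classify_hit,
    default_coordinating_columns,
)
from .seqio import MultipleAlignment, SequenceRecord, extract_peptide
from .splice_detect import (
    DEFAULT_MAX_MISMATCH,
    DEFAULT_MIN_CLUSTER_READS,
    DEFAULT_MIN_OVERLAP_AA,
    DEFAULT_TAIL_LEN_AA,
    IsoformCall,
    anchor_reads,
    cluster_tails,
    locate_junction,
)


@dataclass
class RunConfig:
    """Thresholds and knobs for a pipeline run; defaults are the package defaults."""

    detectors: tuple[str, ...] = ("sw", "hmm")
    sw_min_score: float = DEFAULT_SW_MIN_SCORE
    hmm_report_bits: float = DEFAULT_HMM_REPORT_BITS
    similarity_floor: float = DEFAULT_SIMILARITY_FLOOR
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
    min_overlap_aa: int = DEFAULT_MIN_OVERLAP_AA
    max_mismatch: int = DEFAULT_MAX_MISMATCH
    tail_len_aa: int = DEFAULT_TAIL_LEN_AA
    min_cluster_reads: int = DEFAULT_MIN_CLUSTER_READS
    population_sd: bool = False
    coordinating_columns: list[int] | None = None
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class Analysis:
    hits: list[DomainHit]
    pairs: list[LinkedPair]
    classifications: dict[str, OD1Classification]
    singletons: list[DomainHit]
    evidence: dict[str, TaxonEvidence]
    summary: DistanceSummary | None
    config: RunConfig


def hit_key(h: DomainHit) -> str:
    return f"{h.contig_id}:{h.nt_start}"


def analyze(
    contigs: list[SequenceRecord],
    od1_seed: MultipleAlignment,
    od2_seed: MultipleAlignment,
    config: RunConfig | None = None,
    taxa: dict[str, tuple[str, str]] | None = None,
) -> Analysis:
    """Scan contigs, classify OD1 hits, and aggregate per-taxon evidence.

    ``taxa`` maps contig id to (taxon, order); contigs with their own
    taxon metadata need no entry.  Contigs without any taxon form their
    own single-contig "taxon" under their id.
    """
    config = config or RunConfig()
    taxa = taxa or {}
    for c in contigs:
        if c.taxon is None:
            t = taxa.get(c.id)
            if t:
                c.taxon, c.order_name = t

    od1 = DomainSeeds("OD1", od1_seed)
    od2 = DomainSeeds("OD2", od2_seed)
    hits = scan_contigs(
        contigs, od1, od2,
        detectors=config.detectors,
        sw_min_score=config.sw_min_score,
        hmm_report_bits=config.hmm_report_bits,
    )
    pairs = link_domains(hits)

    coord_cols = config.coordinating_columns or default_coordinating_columns(od1_seed)
    classifications = {
        hit_key(h): classify_hit(
            h.matched_peptide, od1_seed, coord_cols, config.similarity_floor
        )
        for h in hits
        if h.domain == "OD1"
    }

    paired_keys = set()
    for p in pairs:
        paired_keys.add(hit_key(p.od1))
        paired_keys.add(hit_key(p.od2))
    singletons = [h for h in hits if hit_key(h) not in paired_keys]

    by_taxon: dict[str, list] = {}
    orders: dict[str, str] = {}
    for c in contigs:
        t = c.taxon or c.id
        by_taxon.setdefault(t, [])
        orders[t] = c.order_name or ""
    taxon_of = {c.id: (c.taxon or c.id) for c in contigs}

    evidence: dict[str, TaxonEvidence] = {}
    for taxon in sorted(by_taxon):
        t_pairs = [p for p in pairs if taxon_of[p.contig_id] == taxon]
        t_lone = [h for h in singletons if taxon_of[h.contig_id] == taxon]
        evidence[taxon] = categorize_taxon(
            t_pairs, t_lone, classifications, taxon, orders[taxon],
            config.identity_threshold,
        )

    summary = None
    hc_pairs = [p for p in pairs if p.same_frame and not p.tandem_duplicate]
    if hc_pairs:
        summary = distance_summary(
            pairs,
            contig_lengths={c.id: len(c) for c in contigs},
            taxa={cid: t for cid, t in taxon_of.items()},
            population_sd=config.population_sd,
        )
    return Analysis(hits, pairs, classifications, singletons, evidence, summary, config)


def detect_isoforms(
    reads: list[SequenceRecord],
    anchor_contig: SequenceRecord,
    od2_hit: DomainHit,
    od2_seed: MultipleAlignment,
    config: RunConfig | None = None,
) -> IsoformCall:
    """Junction-anchored isoform detection on one OD2-bearing contig."""
    config = config or RunConfig()
    junction_col = locate_junction(od2_seed.consensus())
    pep = od2_hit.matched_peptide
    cut = junction_col if junction_col <= len(pep) else (pep.rfind("E") + 1)
    if cut <= 0:
        raise ValueError("cannot place the junction on the anchor OD2 peptide")
    anchor_prefix = pep[:cut]

    # reference tail read off the anchor contig downstream of the junction
    if od2_hit.strand == "+":
        tail_start = od2_hit.nt_start + 3 * cut
        tail_nt_end = min(len(anchor_contig.residues), tail_start + 3 * (config.tail_len_aa + 2))
        ref_tail = extract_peptide(anchor_contig, tail_start, tail_start + ((tail_nt_end - tail_start) // 3) * 3, "+")
    else:
        tail_end = od2_hit.nt_end - 3 * cut
        tail_nt_start = max(0, tail_end - 3 * (config.tail_len_aa + 2))
        ref_tail = extract_peptide(anchor_contig, tail_end - ((tail_end - tail_nt_start) // 3) * 3, tail_end, "-")
    ref_tail = ref_tail.split("*")[0] or None

    anchored = anchor_reads(
        reads, anchor_prefix,
        min_overlap_aa=config.min_overlap_aa,
        max_mismatch=config.max_mismatch,
    )
    return cluster_tails(
        anchored,
        anchor_id=anchor_contig.id,
        junction_aa=junction_col,
        reference_tail=ref_tail,
        tail_len_aa=config.tail_len_aa,
        min_cluster_reads=config.min_cluster_reads,
    )


# ---------------------------------------------------------------------------
# file-based stage wrappers (the CLI surface)

def _header(config: RunConfig) -> str:
    return f"# dsxscan {__version__} config={config.digest()}\n"


def load_taxon_table(path: str | Path) -> dict[str, tuple[str, str]]:
    taxa = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            taxa[parts[0]] = (parts[1], parts[2] if len(parts) > 2 else "")
    return taxa


def default_seed_alignments() -> tuple[MultipleAlignment, MultipleAlignment]:
    from .synthetic_data import load_od1_seed, load_od2_seed

    return load_od1_seed(), load_od2_seed()


def write_hits_tsv(hits: list[DomainHit], path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("#contig_id\ttaxon\tdomain\tmethod\tframe\tstrand\taa_start\taa_end"
                 "\tnt_start\tnt_end\tscore\tmatched_peptide\n")
        for h in hits:
            fh.write(
                f"{h.contig_id}\t{h.taxon or ''}\t{h.domain}\t{h.method}\t{h.frame:+d}"
                f"\t{h.strand}\t{h.aa_start}\t{h.aa_end}\t{h.nt_start}\t{h.nt_end}"
                f"\t{h.score:.2f}\t{h.matched_peptide}\n"
            )


def write_pairs_tsv(pairs: list[LinkedPair], path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("#contig_id\tod1_nt_start\tod1_nt_end\tod2_nt_start\tod2_nt_end"
                 "\tstrand\tinterdomain_nt\tsame_frame\ttandem_duplicate\n")
        for p in pairs:
            fh.write(
                f"{p.contig_id}\t{p.od1.nt_start}\t{p.od1.nt_end}\t{p.od2.nt_start}"
                f"\t{p.od2.nt_end}\t{p.od1.strand}\t{p.interdomain_nt}"
                f"\t{p.same_frame}\t{p.tandem_duplicate}\n"
            )


def write_classifications_tsv(
    classifications: dict[str, OD1Classification], path: Path, config: RunConfig
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("#hit\tmotif_type\tpos1_4\tpos14_16\tlys14\tlys21\tzf_topology"
                 "\tcoordinating_residues\textra_cys_his\tnotes\n")
        for key in sorted(classifications):
            c = classifications[key]
            fh.write(
                f"{key}\t{c.motif_type}\t{c.pos1_4}\t{c.pos14_16}\t{c.lys14}\t{c.lys21}"
                f"\t{c.zf_topology}\t{c.coordinating_residues}\t{c.extra_cys_his}\t{c.reason}\n"
            )


def write_evidence_tsv(
    evidence: dict[str, TaxonEvidence], path: Path, config: RunConfig
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("#taxon\torder\tcategory\tn_hc_contigs\tn_od1_singletons"
                 "\tn_od2_singletons\tparalogy\tparalogy_basis\tdistances\n")
        for taxon in sorted(evidence):
            e = evidence[taxon]
            fh.write(
                f"{e.taxon}\t{e.order_name}\t{e.category}\t{e.n_hc_contigs}"
                f"\t{e.n_od1_singletons}\t{e.n_od2_singletons}\t{e.paralogy}"
                f"\t{e.paralogy_basis}\t{';'.join(map(str, e.distances))}\n"
            )


def write_distance_tsv(
    analysis: Analysis, contigs: list[SequenceRecord], path: Path
) -> None:
    lengths = {c.id: len(c) for c in contigs}
    taxon_of = {c.id: (c.taxon or c.id) for c in contigs}
    with open(path, "w") as fh:
        fh.write(_header(analysis.config))
        fh.write("#taxon\tcontig_id\tinterdomain_nt\tcontig_length_nt\n")
        for p in analysis.pairs:
            if not p.same_frame or p.tandem_duplicate:
                continue
            fh.write(
                f"{taxon_of.get(p.contig_id, '')}\t{p.contig_id}\t{p.interdomain_nt}"
                f"\t{lengths.get(p.contig_id, 0)}\n"
            )


def write_summary_json(analysis: Analysis, path: Path) -> None:
    s = analysis.summary
    n_cat = {cat: 0 for cat in ("LINKED", "SINGLETONS", "TYPE_B_ONLY", "ABSENT")}
    for e in analysis.evidence.values():
        n_cat[e.category] += 1
    payload = {
        "version": __version__,
        "config": analysis.config.digest(),
        "n_hits": len(analysis.hits),
        "n_pairs": len(analysis.pairs),
        "n_taxa_by_category": n_cat,
        "n_paralogous_taxa": sum(e.paralogy for e in analysis.evidence.values()),
        "distance_summary": None
        if s is None
        else {
            "n": s.n, "mean_nt": s.mean, "sd_nt": s.sd,
            "min": list(s.min), "max_distance": list(s.max_distance),
            "max_fragment": list(s.max_fragment),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_isoform_tsv(call: IsoformCall, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("#anchor_id\tjunction_aa\tcluster_rank\ttail_consensus\tread_count"
                 "\tis_reference\tread_ids\n")
        for rank, c in enumerate(call.clusters, start=1):
            fh.write(
                f"{call.anchor_id}\t{call.junction_aa}\t{rank}\t{c.consensus}"
                f"\t{c.count}\t{call.reference_tail == rank - 1}"
                f"\t{';'.join(c.read_ids)}\n"
            )
        if call.unassigned:
            fh.write(
                f"{call.anchor_id}\t{call.junction_aa}\tunassigned\t.\t"
                f"{len(call.unassigned)}\tFalse\t{';'.join(call.unassigned)}\n"
            )
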