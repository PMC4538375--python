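"""Synthetic transcriptome/genome/read simulator with a ground-truth manifest.

Generates the fixture data every pipeline stage is tested against:
contigs carrying zero, one or two planted OD1/OD2 domains at configurable
spacing, type-A/type-B OD1 motifs, canonical and modified zinc-finger
patterns, paralogous copies at a target amino-acid divergence, fragmented
"genomic" contigs splitting one gene across two sequences, and short
reads spanning an isoform junction immediately downstream of the
conserved OD2 glutamate.  The default configuration is the package's
reference study condition: twelve taxa covering every evidence category
(LINKED / SINGLETONS / TYPE_B_ONLY / ABSENT), both paralogy bases, a
tandem OD2 duplicate, and a two-isoform read set.

Everything is deterministic under the configured seed; the manifest
records each planted feature exactly once and serves as the oracle for
end-to-end tests.

Domain prototypes are a small constructed seed alignment shipped with the
package (``data/od1_seed.afa`` / ``data/od2_seed.afa``); they are
synthetic stand-ins exhibiting the features the classification rules need
(TPPN/RTPK tetrads, Lys14/Lys21, eight Cys/His coordinating columns,
the OD2 double-Leu/Val block and terminal glutamate).  Real seed
alignments are drop-in replacements via configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .domain_scan import BLOSUM62
from .motif_classify import rle_encode
from .seqio import (
    CODON_TABLE,
    MultipleAlignment,
    SequenceRecord,
    read_alignment,
    reverse_complement,
    write_fasta,
    write_fastq,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: 1-based reference columns used by the classifier on the toy OD1 seed
OD1_COORDINATING_COLUMNS = [6, 9, 11, 17, 24, 27, 30, 33]

_AA2CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(CODON_TABLE.items()):
    _AA2CODONS.setdefault(aa, []).append(codon)
NON_STOP_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")


def load_od1_seed() -> MultipleAlignment:
    with resources.as_file(resources.files("dsxscan.data") / "od1_seed.afa") as p:
        return read_alignment(p)


def load_od2_seed() -> MultipleAlignment:
    with resources.as_file(resources.files("dsxscan.data") / "od2_seed.afa") as p:
        return read_alignment(p)


class SimulationError(ValueError):
    pass


# --------------------------------------------------------------------------
# configuration

@dataclass
class GenePlan:
    """One planted gene copy within a taxon."""

    copy_name: str = "copy1"
    motif_type: str = "A"  # "A" | "B"
    zf_residues: str = "CCHHCCCC"  # residues at the 8 coordinating columns
    include_od1: bool = True
    include_od2: bool = True
    interdomain_nt: int = 300
    od1_identity: float = 1.0
    od2_identity: float = 1.0
    strand: str = "+"
    fragmented: bool = False  # split OD1/OD2 onto two "genomic" contigs
    fragment_flank_nt: int = 1550
    stop_downstream_nt: int | None = None  # in-frame stop this far 3' of OD1
    tandem_od2_offset: int | None = None  # second OD2 copy this many nt downstream
    tandem_od2_identity: float = 0.85
    singleton_od2: bool = False  # emit OD2 alone on its own contig
    ref_tail_peptide: str | None = None  # coding tail planted after the OD2 junction
    utr5_nt: int = 90
    utr3_nt: int = 90
    contig_length: int | None = None  # force total length by padding the UTRs


@dataclass
class TaxonPlan:
    taxon: str
    order_name: str
    genes: list[GenePlan] = field(default_factory=list)
    n_background_contigs: int = 0
    background_len: int = 800


@dataclass
class IsoformPlan:
    taxon: str  # anchor taxon (its first gene's contig is the anchor)
    tails: tuple[str, ...] = ("VSQDE", "GKRSL")  # first tail is the reference
    n_reads_per_isoform: int = 30
    n_background_reads: int = 20


@dataclass
class SimConfig:
    seed: int = 20150817
    taxa: list[TaxonPlan] = field(default_factory=list)
    isoform: IsoformPlan | None = None
    read_len_nt: int = 100
    error_rate: float = 0.005
    gc: float = 0.5


def default_config(seed: int = 20150817) -> SimConfig:
    """The reference twelve-taxon study condition."""
    taxa = [
        TaxonPlan("Phasmatodea_sp01", "Phasmatodea",
                  [GenePlan(interdomain_nt=84)]),
        TaxonPlan("Zoraptera_sp02", "Zoraptera",
                  [GenePlan(interdomain_nt=249, zf_residues="CCHHHCCC", strand="-")]),
        TaxonPlan("Protura_sp03", "Protura",
                  [GenePlan("copy1", interdomain_nt=300),
                   GenePlan("copy2", interdomain_nt=150, od1_identity=0.80,
                            od2_identity=0.63, zf_residues="CCHHCCCS")]),
        TaxonPlan("Zygentoma_sp04", "Zygentoma",
                  [GenePlan(interdomain_nt=360),
                   GenePlan("copy2", include_od1=False, singleton_od2=True,
                            od2_identity=0.70)]),
        TaxonPlan("Blattodea_sp05", "Blattodea",
                  [GenePlan(interdomain_nt=3100, fragmented=True)]),
        TaxonPlan("Embioptera_sp06", "Embioptera",
                  [GenePlan(include_od2=False, stop_downstream_nt=423)]),
        TaxonPlan("Isoptera_sp07", "Isoptera",
                  [GenePlan(motif_type="B", include_od2=False)]),
        TaxonPlan("Mantophasmatodea_sp08", "Mantophasmatodea",
                  [], n_background_contigs=1),
        TaxonPlan("Archaeognatha_sp09", "Archaeognatha",
                  [GenePlan(interdomain_nt=213, ref_tail_peptide="VSQDEAGKH")]),
        TaxonPlan("Coleoptera_sp10", "Coleoptera",
                  [GenePlan(interdomain_nt=270, tandem_od2_offset=31)]),
        TaxonPlan("Orthoptera_sp11", "Orthoptera",
                  [GenePlan(interdomain_nt=396, zf_residues="CCHHCHCC")]),
        TaxonPlan("Hymenoptera_sp12", "Hymenoptera",
                  [GenePlan(interdomain_nt=1725, contig_length=6488)]),
    ]
    return SimConfig(seed=seed, taxa=taxa, isoform=IsoformPlan("Archaeognatha_sp09"))


# --------------------------------------------------------------------------
# sequence-level primitives

def _rng_of(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_nt(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def random_inframe_spacer(rng: np.random.Generator, n_nt: int) -> str:
    """A spacer of n_nt (multiple of 3) free of stop codons in its own frame."""
    if n_nt % 3 != 0:
        raise SimulationError("in-frame spacer length must be a multiple of 3")
    return "".join(rng.choice(NON_STOP_CODONS, size=n_nt // 3))


def reverse_translate(rng: np.random.Generator, peptide: str) -> str:
    return "".join(rng.choice(_AA2CODONS[aa]) for aa in peptide)


def mutate_to_identity(
    peptide: str,
    target_identity: float,
    seed,
    protected: frozenset[int] = frozenset(),
) -> str:
    """Substitute residues until the identity to the input hits the target.

    Exactly ``round((1 - target) * len)`` distinct positions are replaced
    with BLOSUM62-plausible (score >= 0) non-identical residues, avoiding
    Cys/His (so no spurious zinc-coordinating residues appear) and the
    ``protected`` positions.  Achieved identity is within 1/len of target.
    """
    if not (0 < target_identity <= 1):
        raise SimulationError("target identity must be in (0, 1]")
    rng = _rng_of(seed)
    n = len(peptide)
    n_sub = round((1 - target_identity) * n)
    if n_sub == 0:
        return peptide
    if target_identity < 1 / n:
        raise SimulationError("target identity below 1/len resolution")
    candidates = [i for i in range(n) if i not in protected]
    if n_sub > len(candidates):
        raise SimulationError("too few unprotected positions for the target identity")
    positions = rng.choice(len(candidates), size=n_sub, replace=False)
    out = list(peptide)
    for ci in sorted(int(p) for p in positions):
        orig = peptide[candidates[ci]]
        plausible = [
            a for a in AA20
            if a != orig and a not in "CH" and float(BLOSUM62[orig, a]) >= 0
        ]
        if not plausible:
            plausible = [a for a in AA20 if a != orig and a not in "CH"]
        out[candidates[ci]] = plausible[int(rng.integers(len(plausible)))]
    return "".join(out)


# --------------------------------------------------------------------------
# domain peptides

def _od1_protected(n: int) -> frozenset[int]:
    cols = {c - 1 for c in OD1_COORDINATING_COLUMNS}
    return frozenset({0, 1, 2, 3, 13, 14, 15, 20, n - 1} | cols)


def _od2_protected(n: int) -> frozenset[int]:
    # termini, the double-Leu/Val block and the junction glutamate
    return frozenset({0, 1, 10, 11, 12, n - 1})


def build_od1_peptide(
    rng: np.random.Generator,
    consensus: str,
    motif_type: str = "A",
    zf_residues: str = "CCHHCCCC",
    identity: float = 1.0,
) -> str:
    pep = list(consensus)
    if motif_type == "B":
        pep[0:4] = "RTPK"
        pep[13:16] = "ISC"
    elif motif_type != "A":
        raise SimulationError(f"unknown motif type {motif_type!r}")
    if len(zf_residues) != len(OD1_COORDINATING_COLUMNS):
        raise SimulationError("zf_residues must cover all coordinating columns")
    for col, res in zip(OD1_COORDINATING_COLUMNS, zf_residues):
        pep[col - 1] = res
    pep = "".join(pep)
    return mutate_to_identity(pep, identity, rng, protected=_od1_protected(len(pep)))


def build_od2_peptide(rng: np.random.Generator, consensus: str, identity: float = 1.0) -> str:
    return mutate_to_identity(consensus, identity, rng, protected=_od2_protected(len(consensus)))


# --------------------------------------------------------------------------
# generation

@dataclass
class SimResult:
    contigs: list[SequenceRecord]
    reads: list[SequenceRecord]
    taxon_table: list[tuple[str, str, str]]  # (contig_id, taxon, order)
    manifest: dict


def _feature(domain, nt_start, nt_end, strand, length, **extra):
    if strand == "+":
        frame = nt_start % 3 + 1
    else:
        frame = -(((length - nt_end) % 3) + 1)
    return {
        "domain": domain,
        "nt_start": int(nt_start),
        "nt_end": int(nt_end),
        "strand": strand,
        "frame": int(frame),
        **extra,
    }


def _zf_topology_of(zf_residues: str) -> str:
    return rle_encode("".join(c for c in zf_residues if c in "CH"))


def generate_dataset(config: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Build the synthetic dataset and its truth manifest.

    Deterministic under ``config.seed``: the same config yields
    byte-identical FASTA/FASTQ/TSV/JSON outputs.
    """
    rng = np.random.default_rng(config.seed)
    od1_consensus = load_od1_seed().consensus()
    od2_consensus = load_od2_seed().consensus()

    contigs: list[SequenceRecord] = []
    taxon_table: list[tuple[str, str, str]] = []
    manifest: dict = {
        "seed": config.seed,
        "od1_consensus": od1_consensus,
        "od2_consensus": od2_consensus,
        "coordinating_columns": OD1_COORDINATING_COLUMNS,
        "contigs": {},
        "taxa": {},
        "reads": None,
    }
    anchor_info: dict | None = None

    for taxon in config.taxa:
        n_hc = 0
        hc_od2_peps: list[str] = []
        singleton_od2_peps: list[str] = []
        has_type_a_singleton = False
        has_type_b = False
        has_od2_singleton = False
        distances: list[int] = []

        for gi, gene in enumerate(taxon.genes):
            cid = f"{taxon.taxon}_c{gi + 1:02d}"
            od1_pep = (
                build_od1_peptide(rng, od1_consensus, gene.motif_type,
                                  gene.zf_residues, gene.od1_identity)
                if gene.include_od1 else None
            )
            od2_pep = (
                build_od2_peptide(rng, od2_consensus, gene.od2_identity)
                if gene.include_od2 else None
            )

            junction_nt = None
            if gene.fragmented:
                recs, feats = _emit_fragmented(rng, cid, gene, od1_pep, od2_pep, config.gc)
            else:
                recs, feats, junction_nt = _emit_contig(rng, cid, gene, od1_pep, od2_pep,
                                                        od2_consensus, config.gc)
            for rec in recs:
                rec.taxon = taxon.taxon
                rec.order_name = taxon.order_name
                contigs.append(rec)
                taxon_table.append((rec.id, taxon.taxon, taxon.order_name))
            for rec_id, flist in feats.items():
                rec = next(r for r in recs if r.id == rec_id)
                entry = {
                    "taxon": taxon.taxon,
                    "order_name": taxon.order_name,
                    "length": len(rec),
                    "features": flist,
                }
                manifest["contigs"][rec_id] = entry

            # expected taxon-level bookkeeping
            linked = (
                gene.include_od1 and gene.include_od2 and not gene.fragmented
                and not gene.singleton_od2 and gene.interdomain_nt % 3 == 0
            )
            if linked:
                n_hc += 1
                hc_od2_peps.append(od2_pep)
                distances.append(gene.interdomain_nt)
            else:
                if gene.include_od1 and gene.motif_type == "A":
                    has_type_a_singleton = True
                if gene.include_od1 and gene.motif_type == "B":
                    has_type_b = True
                if gene.include_od2:
                    has_od2_singleton = True
                    singleton_od2_peps.append(od2_pep)

            if (config.isoform is not None and taxon.taxon == config.isoform.taxon
                    and gi == 0):
                if junction_nt is None or od2_pep is None:
                    raise SimulationError(
                        f"isoform anchor gene in {taxon.taxon!r} has no OD2 junction"
                    )
                anchor_info = {
                    "contig_id": recs[0].id,
                    "cassette": recs[0].residues if gene.strand == "+" else
                    reverse_complement(recs[0].residues),
                    "od2_pep": od2_pep,
                    "junction_nt": junction_nt,
                    "gene": gene,
                }

        for _ in range(taxon.n_background_contigs):
            cid = f"{taxon.taxon}_bg{_ + 1:02d}"
            rec = SequenceRecord(cid, random_nt(rng, taxon.background_len, config.gc), "NT",
                                 taxon=taxon.taxon, order_name=taxon.order_name)
            contigs.append(rec)
            taxon_table.append((cid, taxon.taxon, taxon.order_name))
            manifest["contigs"][cid] = {
                "taxon": taxon.taxon, "order_name": taxon.order_name,
                "length": len(rec), "features": [],
            }

        if n_hc >= 1:
            category = "LINKED"
        elif has_type_a_singleton or has_od2_singleton:
            category = "SINGLETONS"
        elif has_type_b:
            category = "TYPE_B_ONLY"
        else:
            category = "ABSENT"
        paralogy, basis = False, "NONE"
        if n_hc >= 2 and _min_pairwise_identity(hc_od2_peps) < 0.90:
            paralogy, basis = True, "TWO_HC"
        elif n_hc >= 1 and any(
            _hamming_identity(hc_od2_peps[0], s) < 0.90 for s in singleton_od2_peps
        ):
            paralogy, basis = True, "HC_PLUS_DIVERGENT_OD2"
        manifest["taxa"][taxon.taxon] = {
            "order_name": taxon.order_name,
            "category": category,
            "n_hc_contigs": n_hc,
            "paralogy": paralogy,
            "paralogy_basis": basis,
            "distances": sorted(distances),
        }

    reads: list[SequenceRecord] = []
    if config.isoform is not None:
        if anchor_info is None:
            raise SimulationError(
                f"isoform plan names taxon {config.isoform.taxon!r} with no gene"
            )
        reads, read_manifest = _emit_isoform_reads(rng, config, anchor_info)
        manifest["reads"] = read_manifest

    result = SimResult(contigs, reads, taxon_table, manifest)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(contigs, outdir / "contigs.fasta")
        write_fastq(reads, outdir / "reads.fastq")
        with open(outdir / "taxa.tsv", "w") as fh:
            fh.write("#contig_id\ttaxon\torder\n")
            for row in taxon_table:
                fh.write("\t".join(row) + "\n")
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )
    return result


def _min_pairwise_identity(peps: list[str]) -> float:
    best = 1.0
    for i in range(len(peps)):
        for j in range(i + 1, len(peps)):
            best = min(best, _hamming_identity(peps[i], peps[j]))
    return best


def _hamming_identity(a: str, b: str) -> float:
    if len(a) != len(b):
        raise SimulationError("identity comparison needs equal lengths")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _emit_contig(rng, cid, gene: GenePlan, od1_pep, od2_pep, od2_consensus, gc):
    """Assemble one transcript-like contig on the plus strand, then flip if needed."""
    parts: list[str] = []
    features: list[dict] = []
    pos = 0

    utr5, utr3 = gene.utr5_nt, gene.utr3_nt
    if gene.contig_length is not None:
        core = 0
        if od1_pep:
            core += 3 * len(od1_pep)
        if od2_pep:
            core += 3 * len(od2_pep) + gene.interdomain_nt
        if gene.stop_downstream_nt is not None:
            core += gene.stop_downstream_nt + 3
        remainder = gene.contig_length - core
        if remainder < 6:
            raise SimulationError(f"{cid}: forced contig length too short for the gene")
        utr5 = remainder // 2
        utr3 = remainder - utr5

    parts.append(random_nt(rng, utr5, gc))
    pos += utr5

    tail_planted = None
    if od1_pep is not None:
        nt = reverse_translate(rng, od1_pep)
        features.append(("OD1", pos, pos + len(nt),
                         {"motif_type": gene.motif_type,
                          "zf_topology": _zf_topology_of(gene.zf_residues),
                          "identity": gene.od1_identity,
                          "peptide": od1_pep}))
        parts.append(nt)
        pos += len(nt)
        if gene.stop_downstream_nt is not None:
            d = gene.stop_downstream_nt
            if d % 3 != 0:
                raise SimulationError("stop_downstream_nt must be in-frame (multiple of 3)")
            parts.append(random_inframe_spacer(rng, d))
            parts.append("TAA")
            pos += d + 3

    if od2_pep is not None:
        if od1_pep is not None and gene.stop_downstream_nt is None:
            gap = gene.interdomain_nt
            spacer = (random_inframe_spacer(rng, gap) if gap % 3 == 0
                      else random_nt(rng, gap, gc))
            parts.append(spacer)
            pos += gap
        nt = reverse_translate(rng, od2_pep)
        features.append(("OD2", pos, pos + len(nt),
                         {"identity": gene.od2_identity, "peptide": od2_pep}))
        parts.append(nt)
        pos += len(nt)
        tail_planted = pos  # junction: end of the OD2 glutamate codon

        if gene.ref_tail_peptide and gene.tandem_od2_offset is None:
            parts.append(reverse_translate(rng, gene.ref_tail_peptide) + "TAA")
            pos += 3 * len(gene.ref_tail_peptide) + 3

        if gene.tandem_od2_offset is not None:
            off = gene.tandem_od2_offset
            parts.append(random_nt(rng, off, gc))
            pos += off
            pep2 = build_od2_peptide(rng, od2_consensus, gene.tandem_od2_identity)
            nt2 = reverse_translate(rng, pep2)
            features.append(("OD2", pos, pos + len(nt2),
                             {"identity": gene.tandem_od2_identity,
                              "tandem": True, "peptide": pep2}))
            parts.append(nt2)
            pos += len(nt2)

    parts.append(random_nt(rng, utr3, gc))
    pos += utr3

    seq = "".join(parts)
    length = len(seq)
    if gene.strand == "-":
        seq = reverse_complement(seq)
        flipped = []
        for dom, s, e, extra in features:
            flipped.append((dom, length - e, length - s, extra))
        features = flipped
    rec = SequenceRecord(cid, seq, "NT")
    flist = [
        _feature(dom, s, e, gene.strand, length, **extra)
        for dom, s, e, extra in sorted(features, key=lambda f: f[1])
    ]
    return [rec], {rec.id: flist}, tail_planted


def _emit_fragmented(rng, cid, gene: GenePlan, od1_pep, od2_pep, gc):
    """A gene split across two genomic contigs with >=3 kb of intervening sequence."""
    flank = gene.fragment_flank_nt
    recs, meta = [], {}
    if od1_pep is not None:
        nt = reverse_translate(rng, od1_pep)
        seq = random_nt(rng, gene.utr5_nt, gc) + nt + random_nt(rng, flank, gc)
        rec = SequenceRecord(cid + "a", seq, "NT")
        recs.append(rec)
        meta[rec.id] = [
            _feature("OD1", gene.utr5_nt, gene.utr5_nt + len(nt), "+", len(seq),
                     motif_type=gene.motif_type,
                     zf_topology=_zf_topology_of(gene.zf_residues),
                     identity=gene.od1_identity, peptide=od1_pep)
        ]
    if od2_pep is not None:
        nt = reverse_translate(rng, od2_pep)
        seq = random_nt(rng, flank, gc) + nt + random_nt(rng, gene.utr3_nt, gc)
        rec = SequenceRecord(cid + "b", seq, "NT")
        recs.append(rec)
        meta[rec.id] = [
            _feature("OD2", flank, flank + len(nt), "+", len(seq),
                     identity=gene.od2_identity, peptide=od2_pep)
        ]
    return recs, meta


def _apply_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        alternatives = [b for b in "ACGT" if b != out[i]]
        out[i] = alternatives[int(rng.integers(3))]
    return "".join(out)


def _emit_isoform_reads(rng, config: SimConfig, anchor: dict):
    """Reads spanning the junction of two transcript isoforms plus background."""
    plan = config.isoform
    cassette = anchor["cassette"]  # plus-strand transcript of the anchor gene
    junction = anchor["junction_nt"]  # end of the OD2 glutamate codon

    # reference isoform = the anchor contig itself (it carries the planted
    # reference tail); alternative isoforms share the prefix up to the
    # junction then diverge into their own tails
    prefix = cassette[:junction]
    transcripts = {"ref": cassette}
    for k, tail in enumerate(plan.tails[1:], start=1):
        tail_nt = reverse_translate(rng, tail)
        transcripts[f"alt{k}"] = prefix + tail_nt + "TAA" + random_nt(rng, 90, config.gc)

    L = config.read_len_nt
    reads: list[SequenceRecord] = []
    per_read = {}
    lo = junction - (L - 3 * 5)
    hi = junction - 3 * 8
    if lo >= hi or lo < 0:
        raise SimulationError("read length too short to span the junction informatively")
    for label, transcript in sorted(transcripts.items()):
        for k in range(plan.n_reads_per_isoform):
            start = int(rng.integers(lo, hi + 1))
            if start + L > len(transcript):
                raise SimulationError("isoform transcript too short for junction reads")
            raw = transcript[start : start + L]
            rid = f"read_{label}_{k + 1:03d}"
            reads.append(SequenceRecord(rid, _apply_errors(rng, raw, config.error_rate), "NT"))
            per_read[rid] = {"isoform": label, "start": start}
    background = random_nt(rng, 600, config.gc)
    for k in range(plan.n_background_reads):
        start = int(rng.integers(0, len(background) - L))
        rid = f"read_bg_{k + 1:03d}"
        reads.append(SequenceRecord(rid, _apply_errors(rng, background[start : start + L], config.error_rate), "NT"))
        per_read[rid] = {"isoform": "background", "start": start}
    read_manifest = {
        "anchor_contig": anchor["contig_id"],
        "junction_nt": junction,
        "junction_col": len(anchor["od2_pep"]),
        "tails": list(plan.tails),
        "n_isoforms": len(plan.tails),
        "per_read": per_read,
    }
    return reads, read_manifest


def sample_reads(
    rng,
    transcript: str,
    n_reads: int,
    read_len: int = 100,
    error_rate: float = 0.005,
    id_prefix: str = "read",
) -> list[SequenceRecord]:
    """Uniformly sampled substitution-error reads from one transcript."""
    rng = _rng_of(rng)
    if len(transcript) < read_len:
        raise SimulationError("transcript shorter than the read length")
    reads = []
    for k in range(n_reads):
        start = int(rng.integers(0, len(transcript) - read_len + 1))
        raw = transcript[start : start + read_len]
        reads.append(
            SequenceRecord(f"{id_prefix}_{k + 1:04d}", _apply_errors(rng, raw, error_rate), "NT")
        )
    return reads
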