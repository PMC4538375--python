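"""Classify OD1 domain hits: motif type, conserved lysines, zinc-finger topology.

The DM (OD1) domain carries two diagnostic sequence classes.  A *type-A*
motif has a Thr-Pro-Pro-Asn-like tetrad at alignment positions 1-4 and a
conserved lysine at position 14; a *type-B* motif has an
Arg-Thr-Pro-Lys-like tetrad at positions 1-4 and Ile-Ser-Cys beginning at
position 14.  The lysine at position 21 (the DNA salt-bridge residue) is
flagged independently.  "Like" is operationalized as a BLOSUM62 score of
the observed tetrad against the prototype reaching at least
``similarity_floor`` (default 0.5) of the prototype's self-score; the
position-14 anchor is exact and positions 14-16 of a type-B motif must
match Ile-Ser-Cys at 2 of 3.

The zinc-finger topology is the ordered pattern of Cys/His residues at the
eight zinc-coordinating alignment columns, run-length encoded (canonical
``C2H2C4``; modified fingers read e.g. ``C2H2CHC2``, ``C2H3C3``, or
``C2H2C3`` when a coordinating cysteine is lost).  Substituted
(non-Cys/His) residues at coordinating columns drop out of the encoded
string; gapped columns surface as ``?``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .domain_scan import BLOSUM62, sw_align_full
from .seqio import GAP_CHARS, MultipleAlignment

TYPE_A_PROTOTYPE = "TPPN"
TYPE_B_PROTOTYPE = "RTPK"
DEFAULT_SIMILARITY_FLOOR = 0.5

GAP = "-"


@dataclass
class OD1Classification:
    motif_type: str  # "A" | "B" | "UNCLASSIFIED"
    pos1_4: str
    pos14_16: str
    lys14: bool
    lys21: bool
    zf_topology: str
    coordinating_residues: str
    extra_cys_his: int = 0
    reason: str = ""


def rle_encode(s: str) -> str:
    """Run-length encode, leaving single occurrences unnumbered (CCHH -> C2H2)."""
    if not s:
        return ""
    out = []
    run_char, run_len = s[0], 1
    for c in s[1:]:
        if c == run_char:
            run_len += 1
        else:
            out.append(run_char + (str(run_len) if run_len > 1 else ""))
            run_char, run_len = c, 1
    out.append(run_char + (str(run_len) if run_len > 1 else ""))
    return "".join(out)


def rle_decode(s: str) -> str:
    out = []
    i = 0
    while i < len(s):
        c = s[i]
        i += 1
        num = ""
        while i < len(s) and s[i].isdigit():
            num += s[i]
            i += 1
        out.append(c * (int(num) if num else 1))
    return "".join(out)


def _tetrad_score(observed: str, prototype: str) -> float:
    score = 0.0
    for a, b in zip(observed, prototype):
        if a in GAP_CHARS:
            score += -4.0
        else:
            score += float(BLOSUM62[a, b])
    return score


def _self_score(prototype: str) -> float:
    return sum(float(BLOSUM62[c, c]) for c in prototype)


def align_to_od1_reference(
    matched_peptide: str, od1_seed_msa: MultipleAlignment
) -> str | None:
    """Map a hit peptide onto the seed alignment's column coordinate system.

    Returns a gapped string of length ``n_cols`` whose column *i* holds the
    peptide residue aligned to seed column *i* (1-based positions in the
    classification rules index this string).  Alignment is against the seed
    consensus; unaligned peptide flanks are projected positionally onto the
    flanking columns.  Returns ``None`` when the alignment does not reach
    columns 1-21 (classified as UNCLASSIFIED/"incomplete" upstream).
    """
    consensus = od1_seed_msa.consensus()
    n = len(consensus)
    try:
        score, (qs, qe), (ts, te), pairs = sw_align_full(matched_peptide, consensus)
    except Exception:
        return None
    if score <= 0 or not pairs:
        return None
    positioned = [GAP] * n
    for qi, ti in pairs:
        positioned[ti] = matched_peptide[qi]
    # project unaligned flanks column-for-column
    for k in range(1, min(qs, ts) + 1):
        positioned[ts - k] = matched_peptide[qs - k]
    for k in range(min(len(matched_peptide) - qe, n - te)):
        positioned[te + k] = matched_peptide[qe + k]
    s = "".join(positioned)
    if len(s) < 21 or all(c == GAP for c in s[:21]):
        return None
    # require the alignment to actually cover columns 1..21
    covered = [i for i, c in enumerate(s) if c != GAP]
    if not covered or covered[0] > 0 or max(covered) < 20:
        return None
    return s


def classify_od1(
    positioned: str | None,
    coordinating_columns: list[int] | None = None,
    similarity_floor: float = DEFAULT_SIMILARITY_FLOOR,
) -> OD1Classification:
    """Classify a positioned OD1 string into type A / type B / UNCLASSIFIED.

    ``coordinating_columns`` are 1-based alignment columns of the eight
    zinc-coordinating residues; when omitted the topology fields are empty.
    Rules are checked A-then-B and are mutually exclusive (the position-14
    anchors differ).
    """
    if positioned is None or len(positioned) < 21:
        return OD1Classification(
            "UNCLASSIFIED", "", "", False, False, "", "", reason="incomplete"
        )
    pos1_4 = positioned[0:4]
    pos14 = positioned[13]
    pos14_16 = positioned[13:16]
    pos21 = positioned[20]
    lys14 = pos14 == "K"
    lys21 = pos21 == "K"

    motif = "UNCLASSIFIED"
    reason = ""
    floor_a = similarity_floor * _self_score(TYPE_A_PROTOTYPE)
    floor_b = similarity_floor * _self_score(TYPE_B_PROTOTYPE)
    if lys14 and _tetrad_score(pos1_4, TYPE_A_PROTOTYPE) >= floor_a:
        motif = "A"
    elif (
        pos14 == "I"
        and sum(a == b for a, b in zip(pos14_16, "ISC")) >= 2
        and _tetrad_score(pos1_4, TYPE_B_PROTOTYPE) >= floor_b
    ):
        motif = "B"
    else:
        reason = "matches neither motif rule"

    zf = ""
    coord = ""
    extra = 0
    if coordinating_columns:
        zf, coord = zinc_finger_topology(positioned, coordinating_columns, with_residues=True)
        coord_set = set(c - 1 for c in coordinating_columns)
        extra = sum(
            1
            for i, c in enumerate(positioned)
            if c in "CH" and i not in coord_set
        )
    return OD1Classification(
        motif, pos1_4, pos14_16, lys14, lys21, zf, coord, extra_cys_his=extra, reason=reason
    )


def zinc_finger_topology(
    positioned: str,
    coordinating_columns: list[int],
    with_residues: bool = False,
):
    """Run-length-encoded Cys/His pattern at the coordinating columns.

    Residues are read in column order; non-C/H residues (substitutions)
    drop out of the encoded string, gaps become ``?``.
    """
    residues = []
    for col in coordinating_columns:
        if col < 1 or col > len(positioned):
            residues.append("?")
            continue
        c = positioned[col - 1]
        residues.append("?" if c in GAP_CHARS else c)
    reading = "".join(c if c in "CH?" else "." for c in residues)
    topo = rle_encode(reading.replace(".", ""))
    if with_residues:
        return topo, "".join(residues)
    return topo


def default_coordinating_columns(od1_seed_msa: MultipleAlignment) -> list[int]:
    """1-based seed columns whose consensus residue is Cys or His."""
    consensus = od1_seed_msa.consensus()
    return [i + 1 for i, c in enumerate(consensus) if c in "CH"]


def classify_hit(
    matched_peptide: str,
    od1_seed_msa: MultipleAlignment,
    coordinating_columns: list[int] | None = None,
    similarity_floor: float = DEFAULT_SIMILARITY_FLOOR,
) -> OD1Classification:
    """End-to-end: map a hit peptide to seed columns, then classify."""
    if coordinating_columns is None:
        coordinating_columns = default_coordinating_columns(od1_seed_msa)
    positioned = align_to_od1_reference(matched_peptide, od1_seed_msa)
    return classify_od1(positioned, coordinating_columns, similarity_floor)
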