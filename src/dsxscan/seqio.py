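"""Sequence I/O and translation primitives.

Every downstream stage (domain scanning, motif classification, splice
detection) operates on :class:`SequenceRecord` and :class:`TranslatedFrame`
objects produced here.  Conventions used throughout the package:

* nucleotide intervals are 0-based, half-open, on the forward strand;
* amino-acid positions inside domain motifs are 1-based alignment columns
  (so "position 14" means the 14th column of the reference alignment);
* frames are named +1/+2/+3 (forward strand, codon offsets 0/1/2) and
  -1/-2/-3 (reverse complement, offsets 0/1/2), the GenBank convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq

NT_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}
GAP_CHARS = set("-.")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Standard genetic code (NCBI translation table 1).
CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> None:
    bases = "TCAG"
    aas = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                CODON_TABLE[b1 + b2 + b3] = aas[i]
                i += 1


_build_codon_table()


class SequenceError(ValueError):
    """Malformed sequence input."""


@dataclass
class SequenceRecord:
    """A nucleotide or amino-acid sequence with taxon metadata."""

    id: str
    residues: str
    alphabet: str  # "NT" or "AA"
    description: str = ""
    taxon: str | None = None
    order_name: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        if any(c.isspace() for c in self.id):
            raise SequenceError(f"record id {self.id!r} contains whitespace")
        allowed = NT_ALPHABET if self.alphabet == "NT" else AA_ALPHABET
        for pos, c in enumerate(self.residues):
            if c not in allowed:
                raise SequenceError(
                    f"record {self.id!r}: illegal {self.alphabet} character "
                    f"{c!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TranslatedFrame:
    """One reading frame of a nucleotide record.

    ``nt_offset`` is the codon-start offset (0, 1 or 2) within the strand
    the frame reads: the forward strand for +1..+3, the reverse complement
    for -1..-3.  Coordinate mapping back to the forward strand is done by
    :func:`nt_interval_of`.
    """

    source_id: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    peptide: str
    nt_offset: int
    source_length: int

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"


def detect_alphabet(residues: str) -> str:
    """NT if >=90% of characters are ACGTN, else AA."""
    nt = sum(1 for c in residues if c in NT_ALPHABET)
    return "NT" if nt >= 0.9 * len(residues) else "AA"


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into records.

    Residues are uppercased and the alphabet auto-detected per record.
    Duplicate ids and illegal characters are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=residues,
                alphabet=detect_alphabet(residues),
                description=rec.description,
            )
        )
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                desc = rec.description
                if desc.startswith(rec.id):
                    desc = desc[len(rec.id) :].strip()
                if desc:
                    header = f"{rec.id} {desc}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read a 4-line-per-record FASTQ file; qualities are parsed then dropped."""
    records: list[SequenceRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) % 4 != 0:
        raise SequenceError(f"{path}: truncated FASTQ (line count not a multiple of 4)")
    for i in range(0, len(lines), 4):
        head, seq, sep, qual = lines[i : i + 4]
        if not head.startswith("@") or not sep.startswith("+"):
            raise SequenceError(f"{path}: malformed FASTQ record near line {i + 1}")
        if len(seq) != len(qual):
            raise SequenceError(
                f"{path}: sequence/quality length mismatch for {head[1:].split()[0]!r}"
            )
        rid = head[1:].split()[0]
        records.append(SequenceRecord(id=rid, residues=seq.upper(), alphabet="NT"))
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.residues}\n+\n{'I' * len(rec.residues)}\n")


def reverse_complement(nt: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    bad = set(nt) - NT_ALPHABET
    if bad:
        raise SequenceError(f"non-nucleotide characters in input: {sorted(bad)}")
    return nt.translate(_COMPLEMENT)[::-1]


def translate_nt(nt: str) -> str:
    """Translate a nucleotide string codon-by-codon; stops are '*', N-containing codons 'X'."""
    out = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        out.append("X" if "N" in codon else CODON_TABLE[codon])
    return "".join(out)


def six_frame_translate(rec: SequenceRecord) -> list[TranslatedFrame]:
    """All six reading frames of a nucleotide record.

    Frames +1..+3 read the forward strand at offsets 0,1,2; -1..-3 read the
    reverse complement at offsets 0,1,2.  Trailing partial codons are dropped.
    """
    if rec.alphabet != "NT":
        raise SequenceError(f"six_frame_translate requires a nucleotide record, got {rec.alphabet}")
    if len(rec) < 3:
        raise SequenceError(f"record {rec.id!r} shorter than one codon")
    fwd = rec.residues
    rev = reverse_complement(fwd)
    frames = []
    for offset in range(3):
        frames.append(
            TranslatedFrame(rec.id, offset + 1, translate_nt(fwd[offset:]), offset, len(fwd))
        )
    for offset in range(3):
        frames.append(
            TranslatedFrame(rec.id, -(offset + 1), translate_nt(rev[offset:]), offset, len(fwd))
        )
    return frames


def nt_interval_of(frame: TranslatedFrame, aa_start: int, aa_end: int) -> tuple[int, int, str]:
    """Forward-strand nucleotide interval of a half-open peptide slice.

    Returns ``(nt_start, nt_end, strand)`` with ``nt_end - nt_start ==
    3 * (aa_end - aa_start)``.  For minus-strand frames the peptide runs
    right-to-left on the forward strand, so the interval is mirrored.
    """
    if not (0 <= aa_start < aa_end <= len(frame.peptide)):
        raise ValueError(
            f"aa interval [{aa_start},{aa_end}) out of range for peptide of "
            f"length {len(frame.peptide)}"
        )
    L = frame.source_length
    if frame.frame > 0:
        nt_start = frame.nt_offset + 3 * aa_start
        nt_end = frame.nt_offset + 3 * aa_end
        return nt_start, nt_end, "+"
    # on the revcomp strand the slice is [off+3*aa_start, off+3*aa_end);
    # revcomp position p corresponds to forward position L-1-p
    rc_start = frame.nt_offset + 3 * aa_start
    rc_end = frame.nt_offset + 3 * aa_end
    return L - rc_end, L - rc_start, "-"


def extract_peptide(rec: SequenceRecord, nt_start: int, nt_end: int, strand: str) -> str:
    """Translate the forward-strand interval on the given strand (inverse of nt_interval_of)."""
    sub = rec.residues[nt_start:nt_end]
    if strand == "-":
        sub = reverse_complement(sub)
    return translate_nt(sub)


# ---------------------------------------------------------------------------
# seed alignments

@dataclass
class MultipleAlignment:
    """A protein multiple alignment (rows of equal-length gapped strings)."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.rows) < 1:
            raise SequenceError("alignment has no rows")
        n = len(self.rows[0][1])
        for rid, aligned in self.rows:
            if len(aligned) != n:
                raise SequenceError(f"alignment row {rid!r} has inconsistent length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(aligned[j] for _, aligned in self.rows)

    def consensus(self) -> str:
        """Majority residue per column, gaps excluded; ties broken alphabetically.

        Columns that are all-gap are skipped.
        """
        out = []
        for j in range(self.n_cols):
            col = [c for c in self.column(j).upper() if c not in GAP_CHARS]
            if not col:
                continue
            counts: dict[str, int] = {}
            for c in col:
                counts[c] = counts.get(c, 0) + 1
            best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            out.append(best)
        return "".join(out)


def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read an aligned FASTA or Stockholm file (auto-detected)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    fmt = "stockholm" if first.startswith("# STOCKHOLM") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    rows = [(rec.id, str(rec.seq).upper()) for rec in aln]
    return MultipleAlignment(rows=rows)
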