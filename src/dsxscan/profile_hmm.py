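"""Profile hidden Markov model for protein domain search.

A profile HMM is built from a seed multiple alignment: alignment columns
with at least ``match_threshold`` non-gap residues become match states;
residues in the remaining columns are treated as insertions.  Emission and
transition probabilities are maximum-likelihood counts smoothed with a
single-parameter background-mixing pseudocount:

    p = (count + pseudocount * prior) / (total + pseudocount)

where the prior is the background distribution for emissions and uniform
over the outgoing-transition bundle for transitions.

Search is "uni-local" in the HMMER sense: an alignment enters the model at
any match state (uniform probability 1/n over the n match states), runs
through match/insert/delete states, and exits from any match state
(uniform 1/n); the unaligned flanks of the sequence are scored under the
background null, so they contribute zero log-odds.  Scores are reported in
bits (log2 odds of the model versus an i.i.d. background null).

Delete states carry no emission; insert states emit the background
distribution by default, so insertions are score-neutral and act only
through their transition costs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import GAP_CHARS, MultipleAlignment, TranslatedFrame

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA20)}

FORMAT_VERSION = 1
NEG_INF = float("-inf")


class HmmError(ValueError):
    pass


@dataclass
class ProfileHMM:
    """Match/insert emissions and state transitions of a uni-local profile HMM.

    Transition arrays are indexed by match-state number 1..n_match stored at
    offset j-1; entries for the final state are present but unused (exit is
    modelled by the uniform local exit, not by a transition).
    """

    n_match: int
    match_emissions: np.ndarray  # (n_match, 20)
    insert_emissions: np.ndarray  # (n_match, 20)
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    background: np.ndarray  # (20,)
    consensus: str = ""

    # cached log-odds tables, built lazily
    _lm: np.ndarray | None = field(default=None, repr=False, compare=False)
    _li: np.ndarray | None = field(default=None, repr=False, compare=False)

    def _log_tables(self) -> tuple[np.ndarray, np.ndarray]:
        if self._lm is None:
            with np.errstate(divide="ignore"):
                lm = np.log2(self.match_emissions) - np.log2(self.background)
                li = np.log2(self.insert_emissions) - np.log2(self.background)
            # column for 'X' (ambiguous): score-neutral in both state types
            self._lm = np.hstack([lm, np.zeros((self.n_match, 1))])
            self._li = np.hstack([li, np.zeros((self.n_match, 1))])
        return self._lm, self._li

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "dsxscan-profile-hmm",
            "version": FORMAT_VERSION,
            "n_match": self.n_match,
            "alphabet": AA20,
            "consensus": self.consensus,
            "background": self.background.tolist(),
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "transitions": {
                name: getattr(self, name).tolist()
                for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileHMM":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "dsxscan-profile-hmm":
            raise HmmError(f"{path}: not a dsxscan profile HMM file")
        tr = payload["transitions"]
        return cls(
            n_match=payload["n_match"],
            match_emissions=np.array(payload["match_emissions"]),
            insert_emissions=np.array(payload["insert_emissions"]),
            background=np.array(payload["background"]),
            consensus=payload.get("consensus", ""),
            **{name: np.array(tr[name]) for name in tr},
        )


@dataclass
class HmmHit:
    target_id: str
    frame: int
    aa_start: int
    aa_end: int
    bit_score: float
    method: str = "hmm"


def _smooth(counts: np.ndarray, pseudocount: float, prior: np.ndarray) -> np.ndarray:
    total = counts.sum()
    if total + pseudocount == 0:
        return np.asarray(prior, dtype=float).copy()  # unobserved bundle, no smoothing
    return (counts + pseudocount * prior) / (total + pseudocount)


def build_profile(
    msa: MultipleAlignment,
    match_threshold: float = 0.5,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from a seed alignment.

    Columns whose non-gap fraction is >= ``match_threshold`` become match
    states.  Uniform sequence weights; background defaults to uniform 1/20.
    """
    if msa.n_rows < 2:
        raise HmmError("profile construction needs at least 2 alignment rows")
    if background is None:
        background = np.full(20, 1.0 / 20)
    n_rows = msa.n_rows
    match_cols: list[int] = []
    for j in range(msa.n_cols):
        col = msa.column(j).upper()
        nongap = sum(1 for c in col if c not in GAP_CHARS)
        for c in col:
            if c not in GAP_CHARS and c not in AA_INDEX and c != "X":
                raise HmmError(f"alignment column {j + 1}: non-amino-acid residue {c!r}")
        if nongap >= match_threshold * n_rows:
            match_cols.append(j)
    if not match_cols:
        raise HmmError("no alignment column passes the match threshold")

    n = len(match_cols)
    em_counts = np.zeros((n, 20))
    # transition counts per match-state bundle
    c_m = np.zeros((n, 3))  # M -> M, I, D
    c_i = np.zeros((n, 2))  # I -> M, I
    c_d = np.zeros((n, 2))  # D -> M, D

    is_match = [False] * msa.n_cols
    col_to_state = {}
    for k, j in enumerate(match_cols):
        is_match[j] = True
        col_to_state[j] = k

    for _, aligned in msa.rows:
        aligned = aligned.upper()
        # state path of this row across match states 1..n
        prev = None  # (kind, state index k)
        for j, c in enumerate(aligned):
            gap = c in GAP_CHARS
            if is_match[j]:
                k = col_to_state[j]
                kind = "D" if gap else "M"
                if not gap and c != "X":
                    em_counts[k, AA_INDEX[c]] += 1
                if prev is not None:
                    pk, pi = prev
                    if pk == "M":
                        c_m[pi, 0 if kind == "M" else 2] += 1
                    elif pk == "I":
                        c_i[pi, 0] += 1
                    else:
                        c_d[pi, 0 if kind == "M" else 1] += 1
                prev = (kind, k)
            else:
                if gap:
                    continue
                # insert residue, attributed to the insert state after the
                # previous match column (I_k); inserts before the first match
                # column are outside the local model and ignored
                if prev is None:
                    continue
                pk, pi = prev
                if pk == "M":
                    c_m[pi, 1] += 1
                elif pk == "I":
                    c_i[pi, 1] += 1
                else:
                    # delete -> insert has no edge in this topology; the
                    # residue is ignored for transition counting
                    continue
                prev = ("I", pi)

    match_em = np.vstack(
        [_smooth(em_counts[k], pseudocount, background) for k in range(n)]
    )
    insert_em = np.tile(background, (n, 1))

    t_mm = np.empty(n)
    t_mi = np.empty(n)
    t_md = np.empty(n)
    t_im = np.empty(n)
    t_ii = np.empty(n)
    t_dm = np.empty(n)
    t_dd = np.empty(n)
    u3 = np.full(3, 1.0 / 3)
    u2 = np.full(2, 1.0 / 2)
    for k in range(n):
        m = _smooth(c_m[k], pseudocount, u3)
        i = _smooth(c_i[k], pseudocount, u2)
        d = _smooth(c_d[k], pseudocount, u2)
        t_mm[k], t_mi[k], t_md[k] = m
        t_im[k], t_ii[k] = i
        t_dm[k], t_dd[k] = d

    consensus = "".join(AA20[int(np.argmax(em_counts[k]))] if em_counts[k].sum() else "X"
                        for k in range(n))
    return ProfileHMM(
        n_match=n,
        match_emissions=match_em,
        insert_emissions=insert_em,
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_im=t_im, t_ii=t_ii,
        t_dm=t_dm, t_dd=t_dd,
        background=background,
        consensus=consensus,
    )


def _encode(peptide: str) -> np.ndarray:
    idx = np.empty(len(peptide), dtype=np.int64)
    for i, c in enumerate(peptide):
        if c == "X":
            idx[i] = 20
        elif c in AA_INDEX:
            idx[i] = AA_INDEX[c]
        else:
            raise HmmError(f"illegal residue {c!r} in peptide (stops must be split by the caller)")
    return idx


def _log_transitions(model: ProfileHMM) -> dict[str, np.ndarray]:
    with np.errstate(divide="ignore"):
        return {
            name: np.log2(getattr(model, name))
            for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")
        }


def forward_score(model: ProfileHMM, peptide: str) -> float:
    """Forward log-odds score in bits of the best-supported local alignment region.

    Sums over every local alignment path (entry state, emitted substring,
    state path, exit state); unaligned flanks score zero under the null.
    """
    if not peptide:
        raise HmmError("empty peptide")
    x = _encode(peptide)
    lm, li = model._log_tables()
    lt = _log_transitions(model)
    n = model.n_match
    entry = -np.log2(n)
    exit_ = -np.log2(n)

    M = np.full(n, NEG_INF)
    I = np.full(n, NEG_INF)
    D = np.full(n, NEG_INF)
    total = NEG_INF
    for i in range(len(x)):
        e_m = lm[:, x[i]]
        e_i = li[:, x[i]]
        newM = np.full(n, entry)  # fresh local entry at every position
        # continuation from state j-1 at the previous position
        cont = np.full(n, NEG_INF)
        cont[1:] = np.logaddexp2(
            np.logaddexp2(M[:-1] + lt["t_mm"][:-1], I[:-1] + lt["t_im"][:-1]),
            D[:-1] + lt["t_dm"][:-1],
        )
        newM = e_m + np.logaddexp2(newM, cont)
        newI = e_i + np.logaddexp2(M + lt["t_mi"], I + lt["t_ii"])
        newD = np.full(n, NEG_INF)
        for j in range(1, n):
            newD[j] = np.logaddexp2(
                newM[j - 1] + lt["t_md"][j - 1], newD[j - 1] + lt["t_dd"][j - 1]
            )
        M, I, D = newM, newI, newD
        col_end = _log2sum(M + exit_)
        total = np.logaddexp2(total, col_end)
    return float(total)


def _log2sum(v: np.ndarray) -> float:
    m = np.max(v)
    if m == NEG_INF:
        return NEG_INF
    return float(m + np.log2(np.sum(np.exp2(v - m))))


def viterbi_score(model: ProfileHMM, peptide: str) -> tuple[float, int, int]:
    """Best local alignment score in bits and its half-open peptide interval.

    Ties are broken deterministically: earliest start, then shortest interval.
    """
    bits, s, e, _, _ = _viterbi_full(model, peptide)
    return bits, s, e


def _viterbi_full(model: ProfileHMM, peptide: str) -> tuple[float, int, int, int, int]:
    """Viterbi with path anchoring: (bits, aa_start, aa_end, entry_state, exit_state).

    ``entry_state``/``exit_state`` are 0-based match-state indices of the
    first and last aligned model columns, used to extend a trimmed local
    envelope back to the full model span.
    """
    if not peptide:
        raise HmmError("empty peptide")
    x = _encode(peptide)
    lm, li = model._log_tables()
    lt = _log_transitions(model)
    n = model.n_match
    entry = -np.log2(n)
    exit_ = -np.log2(n)
    L = len(x)
    BIG = L + 1

    M = np.full(n, NEG_INF)
    I = np.full(n, NEG_INF)
    D = np.full(n, NEG_INF)
    # per-state best-path anchors: start position and entry match state
    sM = np.full(n, BIG, dtype=np.int64)
    sI = np.full(n, BIG, dtype=np.int64)
    sD = np.full(n, BIG, dtype=np.int64)
    kM = np.zeros(n, dtype=np.int64)
    kI = np.zeros(n, dtype=np.int64)
    kD = np.zeros(n, dtype=np.int64)
    states = np.arange(n, dtype=np.int64)

    best = (NEG_INF, BIG, BIG, 0, 0)  # score, start, end, entry_state, exit_state
    for i in range(L):
        e_m = lm[:, x[i]]
        e_i = li[:, x[i]]
        # candidates for M_j at position i: fresh local entry, M/I/D at (j-1, i-1)
        candM = np.full((4, n), NEG_INF)
        candS = np.full((4, n), BIG, dtype=np.int64)
        candK = np.zeros((4, n), dtype=np.int64)
        candM[0] = entry
        candS[0] = i
        candK[0] = states
        candM[1, 1:] = M[:-1] + lt["t_mm"][:-1]
        candS[1, 1:] = sM[:-1]
        candK[1, 1:] = kM[:-1]
        candM[2, 1:] = I[:-1] + lt["t_im"][:-1]
        candS[2, 1:] = sI[:-1]
        candK[2, 1:] = kI[:-1]
        candM[3, 1:] = D[:-1] + lt["t_dm"][:-1]
        candS[3, 1:] = sD[:-1]
        candK[3, 1:] = kD[:-1]
        bestM = candM.max(axis=0)
        pick = np.argmin(np.where(candM == bestM, candS, BIG), axis=0)
        newSM = candS[pick, states]
        newKM = candK[pick, states]
        newM = e_m + bestM

        candI = np.stack([M + lt["t_mi"], I + lt["t_ii"]])
        candIS = np.stack([sM, sI])
        candIK = np.stack([kM, kI])
        bestI = candI.max(axis=0)
        pick = np.argmin(np.where(candI == bestI, candIS, BIG), axis=0)
        newSI = candIS[pick, states]
        newKI = candIK[pick, states]
        newI = e_i + bestI

        newD = np.full(n, NEG_INF)
        newSD = np.full(n, BIG, dtype=np.int64)
        newKD = np.zeros(n, dtype=np.int64)
        for j in range(1, n):
            a = newM[j - 1] + lt["t_md"][j - 1]
            b = newD[j - 1] + lt["t_dd"][j - 1]
            if a > b or (a == b and newSM[j - 1] <= newSD[j - 1]):
                newD[j], newSD[j], newKD[j] = a, newSM[j - 1], newKM[j - 1]
            else:
                newD[j], newSD[j], newKD[j] = b, newSD[j - 1], newKD[j - 1]
        M, I, D = newM, newI, newD
        sM, sI, sD = newSM, newSI, newSD
        kM, kI, kD = newKM, newKI, newKD

        ends = M + exit_
        top = np.max(ends)
        if top > NEG_INF:
            jpick = int(np.argmin(np.where(ends == top, sM, BIG)))
            cand = (float(top), int(sM[jpick]), i + 1, int(kM[jpick]), jpick)
            if (cand[0] > best[0]
                    or (cand[0] == best[0]
                        and (cand[1], cand[2] - cand[1]) < (best[1], best[2] - best[1]))):
                best = cand
    return best


def _scan_segment(
    model: ProfileHMM, peptide: str, offset: int, report_bits: float, out: list[tuple[float, int, int]]
) -> None:
    # greedy recursive hit extraction: take the best local hit, then rescan
    # the flanking sub-segments so tandem copies in one ORF are all found
    if len(peptide) == 0:
        return
    bits, s, e = viterbi_score(model, peptide)
    if bits < report_bits or s >= e:
        return
    out.append((bits, offset + s, offset + e))
    if s >= 1:
        _scan_segment(model, peptide[:s], offset, report_bits, out)
    if e < len(peptide):
        _scan_segment(model, peptide[e:], offset + e, report_bits, out)


def hmm_scan(
    model: ProfileHMM,
    frames: list[TranslatedFrame],
    report_bits: float = 10.0,
) -> list[HmmHit]:
    """Search translated frames for domain hits scoring >= ``report_bits``.

    Peptides are split at stop codons and each stop-free segment searched;
    overlapping hits on the same frame are merged keeping the best score.
    Results are sorted by (target_id, descending score).
    """
    hits: list[HmmHit] = []
    for fr in frames:
        raw: list[tuple[float, int, int]] = []
        pos = 0
        for seg in fr.peptide.split("*"):
            if seg:
                _scan_segment(model, seg, pos, report_bits, raw)
            pos += len(seg) + 1
        # merge overlapping intervals, best score wins
        raw.sort(key=lambda h: (-h[0], h[1]))
        kept: list[tuple[float, int, int]] = []
        for h in raw:
            if all(h[2] <= k[1] or h[1] >= k[2] for k in kept):
                kept.append(h)
        for bits, s, e in kept:
            hits.append(HmmHit(fr.source_id, fr.frame, s, e, bits))
    hits.sort(key=lambda h: (h.target_id, -h.bit_score, h.frame, h.aa_start))
    return hits
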