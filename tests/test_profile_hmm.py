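"""Profile-HMM construction and scoring, checked against exhaustive path enumeration."""

import math

import numpy as np
import pytest

from dsxscan.profile_hmm import (
    HmmError,
    ProfileHMM,
    build_profile,
    forward_score,
    hmm_scan,
    viterbi_score,
)
from dsxscan.seqio import MultipleAlignment, SequenceRecord, six_frame_translate
from dsxscan.synthetic_data import mutate_to_identity, reverse_translate

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def msa(*rows):
    return MultipleAlignment(rows=[(f"r{i}", r) for i, r in enumerate(rows)])


# ---------------------------------------------------------------------------
# independent oracle: explicit enumeration of every local alignment path

def enumerate_path_odds(model: ProfileHMM, x: str) -> list[float]:
    """Odds ratio of every uni-local path through the model emitting a
    substring of x, by direct recursion over the state graph."""
    n = model.n_match
    bg = model.background
    idx = {a: i for i, a in enumerate(AA20)}

    def em_m(j, c):
        return model.match_emissions[j, idx[c]] / bg[idx[c]]

    def em_i(j, c):
        return model.insert_emissions[j, idx[c]] / bg[idx[c]]

    out: list[float] = []

    def rec(kind, j, i, odds):
        if kind == "M":
            out.append(odds / n)  # exit from any match state
            if j + 1 < n and i < len(x):
                rec("M", j + 1, i + 1, odds * model.t_mm[j] * em_m(j + 1, x[i]))
            if i < len(x):
                rec("I", j, i + 1, odds * model.t_mi[j] * em_i(j, x[i]))
            if j + 1 < n:
                rec("D", j + 1, i, odds * model.t_md[j])
        elif kind == "I":
            if j + 1 < n and i < len(x):
                rec("M", j + 1, i + 1, odds * model.t_im[j] * em_m(j + 1, x[i]))
            if i < len(x):
                rec("I", j, i + 1, odds * model.t_ii[j] * em_i(j, x[i]))
        else:  # D
            if j + 1 < n and i < len(x):
                rec("M", j + 1, i + 1, odds * model.t_dm[j] * em_m(j + 1, x[i]))
            if j + 1 < n:
                rec("D", j + 1, i, odds * model.t_dd[j])

    for k in range(n):
        for s in range(len(x)):
            rec("M", k, s + 1, (1.0 / n) * em_m(k, x[s]))
    return out


def oracle_scores(model, x):
    odds = enumerate_path_odds(model, x)
    return math.log2(sum(odds)), math.log2(max(odds))


class TestBuildProfile:
    def test_hand_computed_pseudocount_emission(self):
        # 2-row alignment, third column half-gapped: still a match column at
        # threshold 0.5; G emission there is (1 + 1*(1/20)) / (1 + 1) = 0.525
        m = build_profile(msa("AC-A", "ACGA"), match_threshold=0.5, pseudocount=1.0)
        assert m.n_match == 4
        g = AA20.index("G")
        assert m.match_emissions[2, g] == pytest.approx(0.525, abs=1e-12)

    def test_zero_pseudocount_limit_concentrates_emissions(self):
        m = build_profile(msa("MKLHAVNRDE", "MKLHAVNRDE", "MKLHAVNRDE"), pseudocount=0.0)
        assert m.n_match == 10
        for j, aa in enumerate("MKLHAVNRDE"):
            assert m.match_emissions[j, AA20.index(aa)] == pytest.approx(1.0)

    def test_half_gap_column_is_match_at_threshold(self):
        m = build_profile(msa("A-A", "AAA"), match_threshold=0.5)
        assert m.n_match == 3

    def test_distributions_normalize_and_are_positive(self, od2_seed):
        m = build_profile(od2_seed)
        assert np.allclose(m.match_emissions.sum(axis=1), 1.0, atol=1e-9)
        assert (m.match_emissions > 0).all()
        bundles = np.stack([m.t_mm + m.t_mi + m.t_md, m.t_im + m.t_ii, m.t_dm + m.t_dd])
        assert np.allclose(bundles, 1.0, atol=1e-9)

    def test_no_match_column_is_error(self):
        with pytest.raises(HmmError):
            build_profile(msa("A---", "-A--"), match_threshold=0.9)

    def test_single_row_is_error(self):
        with pytest.raises(HmmError):
            build_profile(msa("ACD"))


class TestScoring:
    def test_single_state_forced_path_closed_form(self):
        m = build_profile(msa("K", "K", "K"), pseudocount=0.0)
        bits, s, e = viterbi_score(m, "K")
        assert bits == pytest.approx(math.log2(20), abs=1e-9)
        assert (s, e) == (0, 1)
        assert forward_score(m, "K") == pytest.approx(math.log2(20), abs=1e-9)

    def test_self_hit_spans_full_model_and_dominates(self, od2_seed):
        m = build_profile(od2_seed)
        cons = od2_seed.consensus()
        bits, s, e = viterbi_score(m, cons)
        assert (s, e) == (0, len(cons))
        for sub_len in (10, 20, 31):
            sub_bits, _, _ = viterbi_score(m, cons[:sub_len])
            assert sub_bits < bits

    def test_unrelated_composition_scores_below_threshold(self, od2_seed):
        m = build_profile(od2_seed)
        bits, _, _ = viterbi_score(m, "P" * 50)
        assert bits < 10.0

    def test_illegal_residue_is_error(self, od2_seed):
        m = build_profile(od2_seed)
        with pytest.raises(HmmError):
            viterbi_score(m, "KL*PQ")

    @pytest.mark.parametrize("peptide", ["K", "KL", "AKL", "KLMH", "PPPP", "AA"])
    def test_forward_and_viterbi_match_path_enumeration(self, peptide):
        m = build_profile(msa("KLM", "KLM", "KIM", "RLM"), pseudocount=1.0)
        fwd_oracle, vit_oracle = oracle_scores(m, peptide)
        assert forward_score(m, peptide) == pytest.approx(fwd_oracle, abs=1e-9)
        bits, _, _ = viterbi_score(m, peptide)
        assert bits == pytest.approx(vit_oracle, abs=1e-9)

    def test_forward_at_least_viterbi_on_random_peptides(self, od2_seed):
        m = build_profile(od2_seed)
        rng = np.random.default_rng(42)
        for _ in range(25):
            pep = "".join(rng.choice(list(AA20), size=int(rng.integers(5, 80))))
            vit, _, _ = viterbi_score(m, pep)
            assert forward_score(m, pep) >= vit - 1e-12

    def test_consensus_prefix_extension_is_monotone(self, od2_seed):
        m = build_profile(od2_seed)
        cons = od2_seed.consensus()
        prev = float("-inf")
        for k in range(3, len(cons) + 1):
            bits, _, _ = viterbi_score(m, cons[:k])
            assert bits >= prev - 1e-12
            prev = bits


class TestHmmScan:
    def test_planted_consensus_found_at_planted_location(self, od2_seed):
        m = build_profile(od2_seed)
        cons = od2_seed.consensus()
        rng = np.random.default_rng(7)
        nt = reverse_translate(rng, "G" * 30 + cons + "S" * 25)
        rec = SequenceRecord("c1", nt, "NT")
        hits = hmm_scan(m, six_frame_translate(rec))
        assert len(hits) == 1
        h = hits[0]
        assert h.frame == 1 and (h.aa_start, h.aa_end) == (30, 30 + len(cons))

    def test_random_frames_are_hit_free(self, od2_seed):
        m = build_profile(od2_seed)
        rng = np.random.default_rng(20150817)
        from dsxscan.seqio import TranslatedFrame

        frames = [
            TranslatedFrame(f"t{k}", 1, "".join(rng.choice(list(AA20), size=200)), 0, 600)
            for k in range(100)
        ]
        assert hmm_scan(m, frames) == []

    def test_empty_frame_list(self, od2_seed):
        m = build_profile(od2_seed)
        assert hmm_scan(m, []) == []

    def test_planted_divergent_copy_recovered(self, od2_seed):
        m = build_profile(od2_seed)
        cons = od2_seed.consensus()
        diverged = mutate_to_identity(cons, 0.6, 99)
        rng = np.random.default_rng(3)
        rec = SequenceRecord("c", reverse_translate(rng, "A" * 10 + diverged + "G" * 10), "NT")
        hits = hmm_scan(m, six_frame_translate(rec))
        assert [h.frame for h in hits] == [1]


class TestCrossValidation:
    def test_agrees_with_pyhmmer_on_detection(self, od2_seed):
        """An independent HMMER implementation built from the same seed
        agrees on what is and is not a domain hit."""
        pyhmmer = pytest.importorskip("pyhmmer")
        abc = pyhmmer.easel.Alphabet.amino()
        seqs = [
            pyhmmer.easel.TextSequence(name=rid.encode(), sequence=s)
            for rid, s in od2_seed.rows
        ]
        msa = pyhmmer.easel.TextMSA(name=b"od2", sequences=seqs).digitize(abc)
        bg = pyhmmer.plan7.Background(abc)
        hmm, _, _ = pyhmmer.plan7.Builder(abc).build_msa(msa, bg)
        pipe = pyhmmer.plan7.Pipeline(abc, background=bg)
        ours = build_profile(od2_seed)

        rng = np.random.default_rng(6)
        positive = "G" * 8 + mutate_to_identity(od2_seed.consensus(), 0.7, 5) + "S" * 8
        negative = "".join(rng.choice(list(AA20), size=60))
        for pep, expect_hit in ((positive, True), (negative, False)):
            dseq = pyhmmer.easel.TextSequence(name=b"t", sequence=pep).digitize(abc)
            their_hits = pipe.search_hmm(
                hmm, pyhmmer.easel.DigitalSequenceBlock(abc, [dseq])
            )
            our_bits, _, _ = viterbi_score(ours, pep)
            assert (len(their_hits) > 0) == expect_hit
            assert (our_bits >= 15.0) == expect_hit


class TestSerialization:
    def test_json_round_trip(self, od1_seed, tmp_path):
        m = build_profile(od1_seed)
        p = tmp_path / "model.json"
        m.to_json(p)
        back = ProfileHMM.from_json(p)
        assert back.n_match == m.n_match
        assert np.allclose(back.match_emissions, m.match_emissions)
        assert np.allclose(back.t_mm, m.t_mm)
        pep = od1_seed.consensus()
        assert viterbi_score(back, pep) == viterbi_score(m, pep)
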