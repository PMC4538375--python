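"""Smith-Waterman alignment, contig scanning, domain linking."""

import numpy as np
import pytest
from Bio import Align

from dsxscan.domain_scan import (
    BLOSUM62,
    AlignError,
    DomainHit,
    DomainSeeds,
    link_domains,
    scan_contigs,
    stop_codon_downstream,
    sw_align,
)
from dsxscan.seqio import SequenceRecord, reverse_complement
from dsxscan.synthetic_data import mutate_to_identity, random_nt, reverse_translate

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def oracle_sw_score(query, target, matrix=BLOSUM62, gap_open=11.0, gap_extend=1.0):
    """Independent exhaustive DP: gap of length k costs open + k*extend,
    realized as an O(mn(m+n)) max over all gap lengths at each cell."""
    m, n = len(query), len(target)
    S = [[0.0] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = S[i - 1][j - 1] + float(matrix[query[i - 1], target[j - 1]])
            for k in range(1, i + 1):
                s = max(s, S[i - k][j] - gap_open - k * gap_extend)
            for k in range(1, j + 1):
                s = max(s, S[i][j - k] - gap_open - k * gap_extend)
            S[i][j] = max(0.0, s)
            best = max(best, S[i][j])
    return best


class TestSwAlign:
    def test_perfect_self_alignment_is_sum_of_diagonal_scores(self):
        q = "MKKH"
        score, qiv, tiv = sw_align(q, q)
        assert score == sum(float(BLOSUM62[c, c]) for c in q)
        assert qiv == (0, 4) and tiv == (0, 4)

    def test_all_negative_submatrix_floors_at_zero(self):
        # tryptophan against a polyproline stretch: every pairing negative
        score, qiv, tiv = sw_align("WWWW", "PPPPPP")
        assert score == 0.0 and qiv == (0, 0) and tiv == (0, 0)

    def test_illegal_residue_is_error(self):
        with pytest.raises(AlignError):
            sw_align("MK1", "MK")

    def test_matches_independent_exhaustive_dp_on_random_pairs(self):
        rng = np.random.default_rng(2025)
        for _ in range(100):
            q = "".join(rng.choice(list(AA20), size=8))
            t = "".join(rng.choice(list(AA20), size=8))
            score, _, _ = sw_align(q, t)
            assert score == oracle_sw_score(q, t)

    def test_matches_biopython_pairwise_aligner(self):
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = BLOSUM62
        aligner.open_gap_score = -12.0
        aligner.extend_gap_score = -1.0
        rng = np.random.default_rng(11)
        for _ in range(30):
            q = "".join(rng.choice(list(AA20), size=15))
            t = "".join(rng.choice(list(AA20), size=25))
            ours, _, _ = sw_align(q, t)
            assert ours == aligner.score(q, t) or (ours == 0.0 and aligner.score(q, t) <= 0)

    def test_self_alignment_dominates_equal_length_targets(self):
        rng = np.random.default_rng(5)
        x = "".join(rng.choice(list(AA20), size=12))
        self_score, _, _ = sw_align(x, x)
        for _ in range(30):
            y = "".join(rng.choice(list(AA20), size=12))
            other, _, _ = sw_align(x, y)
            assert self_score >= other

    def test_gapped_alignment_beats_interrupted_diagonal(self):
        # deleting one residue must be bridged by an affine gap
        q = "MKLHAVNRDEWQ"
        t = q[:6] + q[7:]
        score, _, _ = sw_align(q, t)
        ungapped = sum(float(BLOSUM62[c, c]) for c in q) - float(BLOSUM62[q[6], q[6]])
        assert score == ungapped - 12.0


@pytest.fixture(scope="module")
def seeds(od1_seed, od2_seed):
    return DomainSeeds("OD1", od1_seed), DomainSeeds("OD2", od2_seed)


def plant_contig(rng, parts):
    """parts: list of (kind, payload) where kind is 'nt' or 'pep'."""
    seq, feats, pos = [], [], 0
    for kind, payload in parts:
        if kind == "nt":
            seq.append(payload)
            pos += len(payload)
        else:
            nt = reverse_translate(rng, payload)
            feats.append((pos, pos + len(nt)))
            seq.append(nt)
            pos += len(nt)
    return "".join(seq), feats


class TestScanContigs:
    def test_planted_domains_recovered_at_exact_coordinates(self, seeds, od1_seed, od2_seed):
        rng = np.random.default_rng(8)
        seq, feats = plant_contig(
            rng,
            [("nt", random_nt(rng, 60)),
             ("pep", od1_seed.consensus()),
             ("nt", "".join(rng.choice(["GCA", "GAA", "CTG"], size=40))),
             ("pep", od2_seed.consensus()),
             ("nt", random_nt(rng, 60))],
        )
        hits = scan_contigs([SequenceRecord("c1", seq, "NT")], *seeds)
        od1_hits = [h for h in hits if h.domain == "OD1"]
        od2_hits = [h for h in hits if h.domain == "OD2"]
        assert len(od1_hits) == 1 and len(od2_hits) == 1
        assert (od1_hits[0].nt_start, od1_hits[0].nt_end) == feats[0]
        assert (od2_hits[0].nt_start, od2_hits[0].nt_end) == feats[1]

    def test_random_contig_is_hit_free(self, seeds):
        rng = np.random.default_rng(13)
        contig = SequenceRecord("r", random_nt(rng, 1200), "NT")
        assert scan_contigs([contig], *seeds) == []

    def test_reverse_strand_domain_reported_on_minus_with_forward_coords(
        self, seeds, od2_seed
    ):
        rng = np.random.default_rng(21)
        seq, feats = plant_contig(
            rng,
            [("nt", random_nt(rng, 45)), ("pep", od2_seed.consensus()),
             ("nt", random_nt(rng, 45))],
        )
        L = len(seq)
        flipped = reverse_complement(seq)
        hits = scan_contigs([SequenceRecord("c", flipped, "NT")], *seeds)
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "-" and h.domain == "OD2"
        s, e = feats[0]
        assert (h.nt_start, h.nt_end) == (L - e, L - s)

    def test_sw_and_hmm_envelopes_agree_on_diverged_domains(self, seeds, od2_seed):
        rng = np.random.default_rng(31)
        pep = mutate_to_identity(od2_seed.consensus(), 0.8, 17)
        seq, feats = plant_contig(
            rng, [("nt", random_nt(rng, 63)), ("pep", pep), ("nt", random_nt(rng, 63))]
        )
        rec = SequenceRecord("c", seq, "NT")
        sw_hits = scan_contigs([rec], *seeds, detectors=("sw",))
        hmm_hits = scan_contigs([rec], *seeds, detectors=("hmm",))
        assert len(sw_hits) == 1 and len(hmm_hits) == 1
        mid_sw = (sw_hits[0].nt_start + sw_hits[0].nt_end) / 2
        mid_hmm = (hmm_hits[0].nt_start + hmm_hits[0].nt_end) / 2
        assert abs(mid_sw - mid_hmm) <= 9


def make_hit(contig, domain, nt_start, nt_end, frame=1, strand="+", score=100.0):
    aa_len = (nt_end - nt_start) // 3
    return DomainHit(contig, domain, frame, strand, 0, aa_len, nt_start, nt_end,
                     score, "sw", "A" * aa_len)


class TestLinkDomains:
    def test_same_frame_pair_distance(self):
        hits = [make_hit("c", "OD1", 30, 96), make_hit("c", "OD2", 180, 324)]
        (pair,) = link_domains(hits)
        assert pair.interdomain_nt == 84
        assert pair.same_frame and not pair.tandem_duplicate

    def test_od2_upstream_is_not_linked(self):
        hits = [make_hit("c", "OD2", 0, 96), make_hit("c", "OD1", 200, 266)]
        assert link_domains(hits) == []

    def test_tandem_od2_in_other_frame_is_supplementary_flagged_pair(self):
        hits = [
            make_hit("c", "OD1", 0, 66),
            make_hit("c", "OD2", 100, 196),
            make_hit("c", "OD2", 226, 322, frame=2),
        ]
        pairs = link_domains(hits)
        assert len(pairs) == 2
        primary, tandem = pairs
        assert primary.interdomain_nt == 34 and primary.same_frame
        assert tandem.tandem_duplicate and not tandem.same_frame
        assert tandem.od2.nt_start - primary.od2.nt_end == 30

    def test_never_links_across_contigs_or_strands(self):
        hits = [
            make_hit("a", "OD1", 0, 66),
            make_hit("b", "OD2", 100, 196),
            make_hit("a", "OD2", 100, 196, strand="-"),
        ]
        assert link_domains(hits) == []

    def test_minus_strand_downstream_is_leftward(self):
        hits = [
            make_hit("c", "OD1", 300, 366, frame=-1, strand="-"),
            make_hit("c", "OD2", 100, 196, frame=-1, strand="-"),
        ]
        (pair,) = link_domains(hits)
        assert pair.interdomain_nt == 300 - 196
        assert pair.same_frame


class TestStopCodonDownstream:
    def test_planted_stop_distance(self, dataset, analysis):
        hit = next(h for h in analysis.hits
                   if h.contig_id.startswith("Embioptera") and h.domain == "OD1")
        contig = next(c for c in dataset.contigs if c.id == hit.contig_id)
        assert stop_codon_downstream(contig, hit) == 423

    def test_adjacent_stop_is_zero(self):
        contig = SequenceRecord("c", "ATGAAATAAGGG", "NT")
        hit = make_hit("c", "OD1", 0, 6)
        assert stop_codon_downstream(contig, hit) == 0

    def test_no_stop_returns_none(self):
        contig = SequenceRecord("c", "ATGAAAGGGGGG", "NT")
        hit = make_hit("c", "OD1", 0, 6)
        assert stop_codon_downstream(contig, hit) is None
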