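"""Junction-anchored splice-isoform detection from translated short reads."""

import random

import numpy as np
import pytest

from dsxscan.seqio import SequenceRecord
from dsxscan.splice_detect import (
    SpliceError,
    anchor_reads,
    cluster_tails,
    count_domain_support,
    locate_junction,
)
from dsxscan.synthetic_data import (
    load_od2_seed,
    mutate_to_identity,
    random_nt,
    reverse_translate,
    sample_reads,
)

OD2 = load_od2_seed().consensus()


class TestLocateJunction:
    def test_terminal_glutamate_of_reference(self):
        assert locate_junction("SSLLVAAE") == 8

    def test_more_c_terminal_of_two_glutamates(self):
        assert locate_junction("AELLVKAEQ") == 8

    def test_planted_junction_column_on_shipped_seed(self):
        # the OD2 reference ends on the junction glutamate
        assert locate_junction(OD2) == len(OD2)

    def test_no_glutamate_is_error(self):
        with pytest.raises(SpliceError):
            locate_junction("SSLLVKAQ")


def reads_over(rng, transcript, starts, read_len=60):
    return [
        SequenceRecord(f"r{k}", transcript[s : s + read_len], "NT")
        for k, s in enumerate(starts)
    ]


@pytest.fixture()
def anchor_setup():
    rng = np.random.default_rng(99)
    anchor = OD2  # peptide ending at the junction
    prefix_nt = reverse_translate(rng, anchor)
    return rng, anchor, prefix_nt


class TestAnchorReads:
    def test_verbatim_read_anchors_without_mismatch(self, anchor_setup):
        rng, anchor, prefix_nt = anchor_setup
        tail_nt = reverse_translate(rng, "VSQDEAG")
        transcript = prefix_nt + tail_nt
        reads = reads_over(rng, transcript, [len(prefix_nt) - 36])
        (a,) = anchor_reads(reads, anchor)
        assert a.mismatches == 0 and a.tail.startswith("VSQDE")
        assert a.informative and a.nt_consistent

    def test_unrelated_read_does_not_anchor(self, anchor_setup):
        rng, anchor, _ = anchor_setup
        reads = [SequenceRecord("x", random_nt(rng, 90), "NT") for _ in range(30)]
        assert anchor_reads(reads, anchor) == []

    def test_read_ending_at_junction_is_uninformative(self, anchor_setup):
        rng, anchor, prefix_nt = anchor_setup
        reads = reads_over(rng, prefix_nt, [len(prefix_nt) - 60])
        (a,) = anchor_reads(reads, anchor)
        assert a.overlap_aa >= 8 and not a.informative

    def test_raising_mismatch_budget_is_monotone(self, anchor_setup):
        rng, anchor, prefix_nt = anchor_setup
        transcript = prefix_nt + reverse_translate(rng, "VSQDEAG")
        raw = [transcript[s : s + 60] for s in range(0, len(transcript) - 60, 7)]
        reads = []
        for k, r in enumerate(raw):  # salt with scattered substitutions
            pos = int(rng.integers(len(r)))
            alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[r[pos]]
            reads.append(SequenceRecord(f"m{k}", r[:pos] + alt + r[pos + 1 :], "NT"))
        counts = [len(anchor_reads(reads, anchor, max_mismatch=mm)) for mm in (0, 1, 2, 3)]
        assert counts == sorted(counts)


class TestClusterTails:
    def _anchored(self, tails_with_counts, rng):
        reads = []
        prefix_nt = reverse_translate(rng, OD2)
        for tail, count in tails_with_counts:
            transcript = prefix_nt + reverse_translate(rng, tail)
            for k in range(count):
                reads.append(
                    SequenceRecord(
                        f"r_{tail}_{k}", transcript[len(prefix_nt) - 45 :], "NT"
                    )
                )
        return anchor_reads(reads, OD2)

    def test_uniform_tails_give_single_cluster_no_call(self):
        rng = np.random.default_rng(1)
        anchored = self._anchored([("VSQDE", 20)], rng)
        call = cluster_tails(anchored, "c", 32, reference_tail="VSQDE")
        assert len(call.clusters) == 1 and not call.alternative_called
        assert call.reference_tail == 0

    def test_two_supported_tails_call_an_alternative_isoform(self):
        rng = np.random.default_rng(2)
        anchored = self._anchored([("VSQDE", 10), ("GKRSL", 10)], rng)
        call = cluster_tails(anchored, "c", 32, reference_tail="VSQDE")
        assert call.alternative_called
        assert sorted(c.consensus for c in call.clusters) == ["GKRSL", "VSQDE"]
        assert all(c.count == 10 for c in call.clusters)

    def test_single_divergent_read_stays_unassigned(self):
        rng = np.random.default_rng(3)
        anchored = self._anchored([("VSQDE", 10), ("GKRSL", 1)], rng)
        call = cluster_tails(anchored, "c", 32, min_cluster_reads=2)
        assert len(call.clusters) == 1 and not call.alternative_called
        assert len(call.unassigned) == 1

    def test_clusters_partition_informative_reads(self):
        rng = np.random.default_rng(4)
        anchored = self._anchored([("VSQDE", 7), ("GKRSL", 5), ("NNTPA", 1)], rng)
        call = cluster_tails(anchored, "c", 32)
        clustered = [r for c in call.clusters for r in c.read_ids]
        assert len(set(clustered)) == len(clustered)
        assert sorted(clustered + call.unassigned) == sorted(
            r.read_id for r in anchored if r.informative
        )

    def test_clustering_is_order_invariant(self):
        rng = np.random.default_rng(5)
        anchored = self._anchored([("VSQDE", 6), ("GKRSL", 6)], rng)
        ref = cluster_tails(anchored, "c", 32)
        shuffler = random.Random(0)
        for _ in range(5):
            shuffled = anchored[:]
            shuffler.shuffle(shuffled)
            call = cluster_tails(shuffled, "c", 32)
            assert [(c.consensus, c.read_ids) for c in call.clusters] == [
                (c.consensus, c.read_ids) for c in ref.clusters
            ]


class TestCountDomainSupport:
    def test_no_reads_counts_zero(self):
        assert count_domain_support([], OD2) == 0

    def test_region_shorter_than_overlap_is_error(self):
        with pytest.raises(SpliceError):
            count_domain_support([], "SHORT")

    def test_coverage_count_matches_expectation(self):
        rng = np.random.default_rng(10)
        flank5, flank3 = random_nt(rng, 150), random_nt(rng, 150)
        transcript = flank5 + reverse_translate(rng, OD2) + flank3
        read_len, n_reads = 90, 400
        reads = sample_reads(rng, transcript, n_reads, read_len=read_len, error_rate=0.0)
        count = count_domain_support(reads, OD2)
        region_nt = 3 * len(OD2)
        # a read must overlap the region by >= 24 nt (8 aa) to count
        eligible_starts = (len(transcript) - read_len + 1)
        window = (region_nt + read_len - 2 * 24)
        expected = n_reads * window / eligible_starts
        assert count == pytest.approx(expected, rel=0.2)

    def test_reads_from_one_copy_do_not_count_for_divergent_copy(self):
        rng = np.random.default_rng(11)
        copy2 = mutate_to_identity(OD2, 0.6, 55)
        transcript = random_nt(rng, 60) + reverse_translate(rng, OD2) + random_nt(rng, 60)
        reads = sample_reads(rng, transcript, 150, read_len=90, error_rate=0.0)
        assert count_domain_support(reads, OD2) > 0
        assert count_domain_support(reads, copy2, max_mismatch=1) == 0
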