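import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organrep import (
    SequenceRecord,
    ValidationError,
    assign_clones,
    cluster_clonotypes,
    evenness_profile,
    expansion_profile,
    hill_diversity,
    shm_load,
)
from conftest import make_clone


def rec(sid, organ, v="IGHV1-1", j="IGHJ2", cdrh3="CARDYW", count=1, mouse="m1", **kw):
    return SequenceRecord(sid, organ, v, j, cdrh3, count=count, mouse_id=mouse, **kw)


class TestAssignClones:
    def test_same_key_two_organs_is_one_clone(self):
        rep = assign_clones([rec("s1", "BM"), rec("s2", "spleen")])
        assert len(rep) == 1
        assert rep.clones[0].organs == {"BM", "spleen"}

    def test_j_gene_difference_splits_clones(self):
        rep = assign_clones([rec("s1", "BM", j="IGHJ1"), rec("s2", "BM", j="IGHJ2")])
        assert len(rep) == 2

    def test_frequency_normalization(self):
        # two keys with counts 3+2 and 3+2 in one organ -> 0.5 each
        records = [
            rec("s1", "BM", cdrh3="CARDYW", count=3),
            rec("s2", "BM", cdrh3="CARDYW", count=2),
            rec("s3", "BM", cdrh3="CARGGW", count=3),
            rec("s4", "BM", cdrh3="CARGGW", count=2),
        ]
        rep = assign_clones(records)
        assert sorted(c.frequencies["BM"] for c in rep.clones) == [0.5, 0.5]

    def test_allele_calls_are_stripped(self):
        rep = assign_clones([rec("s1", "BM", v="IGHV1-1*01"), rec("s2", "BM", v="IGHV1-1*02")])
        assert len(rep) == 1 and rep.clones[0].v_gene == "IGHV1-1"

    def test_paired_mode_uses_light_chain(self):
        a = rec("s1", "BM", cdrl3_aa="CQQYW")
        b = rec("s2", "BM", cdrl3_aa="CQQFW")
        assert len(assign_clones([a, b], mode="paired")) == 2
        with pytest.raises(ValidationError):
            assign_clones([rec("s1", "BM")], mode="paired")

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            assign_clones([])

    def test_frequencies_sum_to_one_per_organ(self, rng):
        records = [
            rec(f"s{i}", rng.choice(["BM", "spleen", "aLN-L"]),
                cdrh3="CAR" + "".join(rng.choice(list("ADGW"), 4)) + "W",
                count=int(rng.integers(1, 9)))
            for i in range(100)
        ]
        rep = assign_clones(records)
        for organ in rep.organs:
            total = sum(c.frequencies[organ] for c in rep.organ_clones(organ))
            assert math.isclose(total, 1.0, abs_tol=1e-9)


class TestClusterClonotypes:
    def test_identity_below_threshold_separates(self):
        # length 6, 1 mismatch -> identity 5/6 ~ 0.833 < 0.9
        a, b = make_clone(cdrh3="CARDYW"), make_clone(cdrh3="CARDFW")
        cluster_clonotypes([a, b], 0.90)
        assert a.clonotype_id != b.clonotype_id

    def test_identity_above_threshold_joins(self):
        # length 12, 1 mismatch -> identity 11/12 ~ 0.917 > 0.9
        a = make_clone(cdrh3="CARDYYGSSYWF")
        b = make_clone(cdrh3="CARDYYGSSYWW")
        cluster_clonotypes([a, b], 0.90)
        assert a.clonotype_id == b.clonotype_id

    def test_different_v_gene_never_links(self):
        a = make_clone(v="IGHV1-1", cdrh3="CARDYYGSSYWF")
        b = make_clone(v="IGHV1-2", cdrh3="CARDYYGSSYWF")
        cluster_clonotypes([a, b], 0.01)
        assert a.clonotype_id != b.clonotype_id

    def test_inclusive_boundary_flag(self):
        # length 10, 1 mismatch: identity exactly 0.9
        a, b = make_clone(cdrh3="CARDYGSSYW"), make_clone(cdrh3="CARDFGSSYW")
        cluster_clonotypes([a, b], 0.90)
        assert a.clonotype_id != b.clonotype_id
        cluster_clonotypes([a, b], 0.90, inclusive=True)
        assert a.clonotype_id == b.clonotype_id

    def test_single_linkage_chains_through_intermediates(self):
        seqs = ["CARDYYGSSYWF", "CARDYYGSSYWW", "CARDYYGSSYGW"]
        clones = [make_clone(cdrh3=s) for s in seqs]
        cluster_clonotypes(clones, 0.90)
        assert len({c.clonotype_id for c in clones}) == 1


class TestExpansionProfile:
    def test_uniform_bins(self):
        freqs = {("V", "J", f"C{i:02d}W"): 0.1 for i in range(10)}
        profile = expansion_profile(freqs, [3, 10])
        assert [round(v, 10) for _, v in profile] == [0.3, 0.7]

    def test_exhaustive_bin(self):
        freqs = dict(zip([("V", "J", c) for c in ("CAW", "CBW", "CCW")], (0.5, 0.3, 0.2)))
        assert expansion_profile(freqs, [3]) == [("1-3", 1.0)]

    def test_hand_summed_bins(self):
        freqs = dict(
            zip([("V", "J", c) for c in ("CAW", "CBW", "CCW", "CDW")], (0.4, 0.3, 0.2, 0.1))
        )
        profile = expansion_profile(freqs, [2, 4])
        assert [(lbl, round(v, 10)) for lbl, v in profile] == [("1-2", 0.7), ("3-4", 0.3)]

    def test_empty_repertoire(self):
        assert expansion_profile({}, [3]) == []

    def test_bins_partition_and_sum_to_one(self, rng):
        f = rng.dirichlet(np.ones(23))
        freqs = {("V", "J", f"C{i:03d}W"): x for i, x in enumerate(f)}
        profile = expansion_profile(freqs, [1, 5, 10])
        assert math.isclose(sum(v for _, v in profile), 1.0, abs_tol=1e-9)


class TestHillDiversity:
    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0, 2.0, 7.3])
    def test_uniform_gives_richness(self, alpha):
        f = np.full(7, 1 / 7)
        assert math.isclose(hill_diversity(f, alpha), 7.0, rel_tol=1e-12)

    def test_order_two_closed_form(self):
        # (0.75^2 + 0.25^2)^(1/(1-2)) = 1/0.625 = 1.6
        assert math.isclose(hill_diversity([0.75, 0.25], 2.0), 1.6, rel_tol=1e-12)

    def test_shannon_limit_fair_coin(self):
        assert math.isclose(hill_diversity([0.5, 0.5], 1.0), 2.0, rel_tol=1e-12)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValidationError):
            hill_diversity([0.5, 0.4], 2.0)
        with pytest.raises(ValidationError):
            hill_diversity([1.2, -0.2], 2.0)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=30), st.integers(0, 10**6))
    def test_monotone_nonincreasing_in_alpha(self, weights, _seed):
        f = np.asarray(weights) / np.sum(weights)
        alphas = [0.0, 0.3, 0.7, 1.0, 1.5, 2.0, 4.0, 10.0]
        d = [hill_diversity(f, a) for a in alphas]
        assert all(d[i] >= d[i + 1] - 1e-9 for i in range(len(d) - 1))

    def test_continuity_at_shannon_point(self, rng):
        for _ in range(50):
            f = rng.dirichlet(np.ones(rng.integers(2, 40)))
            d1 = hill_diversity(f, 1.0)
            assert abs(hill_diversity(f, 1.0 - 1e-5) - d1) < 1e-3
            assert abs(hill_diversity(f, 1.0 + 1e-5) - d1) < 1e-3


class TestEvennessProfile:
    def test_uniform_distribution_is_maximally_even(self):
        prof = evenness_profile(np.full(12, 1 / 12))
        assert np.allclose(prof.evenness, 1.0)
        assert prof.richness == 12

    def test_zero_order_evenness_is_always_one(self, rng):
        prof = evenness_profile(rng.dirichlet(np.ones(9)), alpha_grid=[0.0, 1.0, 2.0])
        assert math.isclose(prof.evenness[0], 1.0, rel_tol=1e-12)

    def test_dominant_clone_drives_evenness_down(self):
        prof = evenness_profile([0.999, 0.001], alpha_grid=[2.0])
        # D(2) = 1/(0.999^2 + 0.001^2) ~ 1.002 -> E ~ 0.501
        assert math.isclose(prof.evenness[0], 1.002 / 2, rel_tol=1e-3)

    def test_single_clone_degenerate(self):
        prof = evenness_profile([1.0], alpha_grid=[0.0, 1.0, 2.0])
        assert np.allclose(prof.evenness, 1.0)


class TestShmLoad:
    def test_identical_sequences(self):
        assert shm_load("ACGT" * 80, "ACGT" * 80) == 0.0

    def test_three_mismatches_over_300(self):
        germ = "A" * 300
        seq = "T" * 3 + "A" * 297
        assert math.isclose(shm_load(seq, germ, region_end=300), 0.01)

    def test_ambiguous_positions_masked(self):
        germ = "A" * 312
        seq = "T" + "N" * 10 + "A" * 301
        assert math.isclose(shm_load(seq, germ), 1 / 302)

    def test_no_comparable_positions(self):
        assert shm_load("N" * 10, "A" * 10) is None
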