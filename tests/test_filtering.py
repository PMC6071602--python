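"""Filter stages: thresholds, exact HWE test, Mendelian checks, VIF pruning."""

import itertools
import math

import numpy as np
import pytest

from radpop import (
    MISSING,
    Pedigree,
    ScaffoldIndex,
    SimulationConfig,
    cascade,
    drop_high_missing_individuals,
    filter_call_rate,
    filter_hwe,
    filter_maf,
    filter_mendel,
    hwe_exact_p,
    mask_by_depth,
    mendel_errors,
    restrict_scaffolds,
    simulate_inbred_genotypes,
    simulate_trios,
    vif_prune,
)
from radpop.filtering import _window_vifs

from conftest import make_matrix


class TestDepthMask:
    def test_bounds_inclusive(self):
        calls = [[1, 1, 1, 1]]
        depths = [[7, 8, 30, 31]]
        G, rep = mask_by_depth(make_matrix(calls, depths), 8, 30)
        assert list(G.calls[0]) == [MISSING, 1, 1, MISSING]
        assert rep.loci_after == rep.loci_before == 4

    def test_in_range_depths_untouched(self):
        G0 = make_matrix([[0, 1], [2, 1]], [[20, 20], [20, 20]])
        G, _ = mask_by_depth(G0, 8, 30)
        assert np.array_equal(G.calls, G0.calls)

    def test_requires_depths(self):
        with pytest.raises(ValueError, match="DP"):
            mask_by_depth(make_matrix([[0, 1]]), 8, 30)


class TestThresholdFilters:
    def test_maf_strictly_less_than_removed(self):
        # locus 0: alt freq 0.09 -> removed at 0.1; locus 1: maf exactly 0.1 kept
        calls = np.zeros((50, 2), dtype=np.int8)
        calls[:9, 0] = 1  # alt count 9/100 = 0.09
        calls[:10, 1] = 1  # 0.10
        G, _ = filter_maf(make_matrix(calls), 0.1)
        assert G.n_loci == 1 and G.loci.iloc[0]["maf"] == pytest.approx(0.1)

    def test_monomorphic_removed_at_any_positive_threshold(self):
        G, _ = filter_maf(make_matrix([[0], [0]]), 1e-9)
        assert G.n_loci == 0

    def test_call_rate_strict_inequality(self):
        calls = np.ones((100, 2), dtype=np.int8)
        calls[:51, 0] = MISSING  # call rate 0.49
        calls[:50, 1] = MISSING  # call rate 0.50
        G, _ = filter_call_rate(make_matrix(calls), 0.5)
        assert G.n_loci == 1 and G.loci.iloc[0]["call_rate"] == pytest.approx(0.5)

    def test_fully_typed_locus_survives_any_threshold(self):
        G, _ = filter_call_rate(make_matrix([[1], [2]]), 1.0)
        assert G.n_loci == 1

    def test_high_missing_individual_dropped_strictly(self):
        calls = np.ones((3, 100), dtype=np.int8)
        calls[0, :91] = MISSING  # 91% missing -> dropped
        calls[1, :90] = MISSING  # exactly 90% -> kept
        G, _ = drop_high_missing_individuals(make_matrix(calls), 0.9)
        assert G.individual_ids == ["ind1", "ind2"]


class TestRestrictScaffolds:
    def test_keeps_longest(self):
        G0 = make_matrix([[1, 1]], scaffold=["s_long", "s_short"])
        idx = ScaffoldIndex({"s_long": 100, "s_short": 50})
        G, _ = restrict_scaffolds(G0, idx, 1)
        assert list(G.loci["scaffold"]) == ["s_long"]
        G_all, _ = restrict_scaffolds(G0, idx, 2)
        assert G_all.n_loci == 2

    def test_rank_cutoff_on_many_scaffolds(self):
        n = 150
        scaffolds = [f"s{i:03d}" for i in range(n)]
        idx = ScaffoldIndex({s: 1000 + i for i, s in enumerate(scaffolds)})
        G0 = make_matrix(
            np.ones((2, n), dtype=np.int8), scaffold=scaffolds, positions=np.arange(n) + 1
        )
        G, _ = restrict_scaffolds(G0, idx, 100)
        # longest 100 are the highest-numbered labels
        assert G.n_loci == 100
        assert min(G.loci["scaffold"]) == "s050"

    def test_unknown_scaffold_errors(self):
        G0 = make_matrix([[1]], scaffold="mystery")
        with pytest.raises(KeyError, match="mystery"):
            restrict_scaffolds(G0, ScaffoldIndex({"s1": 10}), 1)


def brute_force_hwe(n_AA, n_Aa, n_aa):
    """Exact test by full enumeration of genotype configurations."""
    n = n_AA + n_Aa + n_aa
    n_alt = 2 * n_aa + n_Aa
    probs = {}
    for het in range(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2):
        aa = (n_alt - het) // 2
        AA = n - het - aa
        if AA < 0:
            continue
        w = math.factorial(n) // (
            math.factorial(AA) * math.factorial(het) * math.factorial(aa)
        ) * 2**het
        probs[het] = w
    total = sum(probs.values())
    obs = probs[n_Aa] / total
    return sum(v / total for v in probs.values() if v / total <= obs * (1 + 1e-12))


class TestHweExact:
    def test_worked_examples(self):
        assert hwe_exact_p(1, 0, 1) == pytest.approx(1 / 3)
        assert hwe_exact_p(0, 2, 0) == pytest.approx(1.0)
        assert hwe_exact_p(5, 0, 0) == 1.0  # monomorphic: single outcome

    def test_matches_enumeration_for_all_small_configurations(self):
        for n in range(1, 11):
            for n_aa in range(n + 1):
                for n_het in range(n - n_aa + 1):
                    n_AA = n - n_aa - n_het
                    assert hwe_exact_p(n_AA, n_het, n_aa) == pytest.approx(
                        brute_force_hwe(n_AA, n_het, n_aa)
                    ), (n_AA, n_het, n_aa)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)


class TestHweFilter:
    def test_removal_below_alpha(self):
        # 40 individuals, all het: p well below 0.001
        calls = np.ones((40, 1), dtype=np.int8)
        G, _ = filter_hwe(make_matrix(calls), 0.001)
        assert G.n_loci == 0

    def test_monomorphic_in_every_group_retained(self):
        calls = np.zeros((10, 1), dtype=np.int8)
        groups = {f"ind{i}": "p1" if i < 5 else "p2" for i in range(10)}
        G, _ = filter_hwe(make_matrix(calls), 0.001, groups)
        assert G.n_loci == 1

    def test_any_group_rule(self):
        # group p1: 20 individuals all het (out of HWE); p2: exact HW proportions
        calls = np.zeros((40, 1), dtype=np.int8)
        calls[:20, 0] = 1
        calls[20:25, 0] = 0
        calls[25:35, 0] = 1
        calls[35:40, 0] = 2
        G0 = make_matrix(calls)
        groups = {f"ind{i}": "p1" if i < 20 else "p2" for i in range(40)}
        in_any, _ = filter_hwe(G0, 0.001, groups)
        pooled_only, _ = filter_hwe(G0.select_individuals([f"ind{i}" for i in range(20, 40)]), 0.001)
        assert in_any.n_loci == 0  # removed because p1 fails
        assert pooled_only.n_loci == 1  # p2 alone is fine


GAMETES = {0: {0}, 1: {0, 1}, 2: {1}}


class TestMendel:
    @pytest.mark.parametrize("gm,gf", list(itertools.product(range(3), repeat=2)))
    def test_full_trio_truth_table(self, gm, gf):
        possible = {a + b for a in GAMETES[gm] for b in GAMETES[gf]}
        for gc in range(3):
            G = make_matrix([[gm], [gf], [gc]], ids=["m", "f", "c"])
            errs = mendel_errors(G, Pedigree([("c", "m", "f")]))
            assert errs[0] == (0 if gc in possible else 1), (gm, gf, gc)

    @pytest.mark.parametrize("gp", range(3))
    def test_duo_truth_table(self, gp):
        for gc in range(3):
            G = make_matrix([[gp], [gc]], ids=["m", "c"])
            errs = mendel_errors(G, Pedigree([("c", "m", None)]))
            expected = 1 if (gp, gc) in {(0, 2), (2, 0)} else 0
            assert errs[0] == expected

    def test_missing_parent_call_falls_back_to_duo(self):
        G = make_matrix([[MISSING], [2], [0]], ids=["m", "f", "c"])
        errs = mendel_errors(G, Pedigree([("c", "m", "f")]))
        assert errs[0] == 1

    def test_locus_with_error_removed(self):
        G = make_matrix([[0, 1], [0, 1], [1, 1]], ids=["m", "f", "c"])
        G2, _ = filter_mendel(G, Pedigree([("c", "m", "f")]))
        assert G2.n_loci == 1

    def test_error_free_simulated_trios_remove_nothing(self):
        parents, _ = simulate_inbred_genotypes(
            SimulationConfig(n_individuals=10, n_loci=50, seed=2, f_model="constant")
        )
        G, ped, _ = simulate_trios(parents, 5, mendel_error_rate=0.0, seed=3)
        G2, _ = filter_mendel(G, ped)
        assert G2.n_loci == G.n_loci

    def test_injected_errors_recovered_exactly(self):
        parents, _ = simulate_inbred_genotypes(
            SimulationConfig(n_individuals=10, n_loci=80, seed=4, f_model="constant")
        )
        G, ped, injected = simulate_trios(parents, 6, mendel_error_rate=0.05, seed=5)
        assert injected  # sanity: some errors were injectable
        errs = mendel_errors(G, ped)
        assert set(np.flatnonzero(errs)) == {j for _, j in injected}

    def test_empty_pedigree_is_identity_with_warning(self):
        G = make_matrix([[0, 1], [1, 2]])
        with pytest.warns(UserWarning, match="empty pedigree"):
            G2, _ = filter_mendel(G, Pedigree([]))
        assert G2.n_loci == 2


class TestVifPrune:
    def test_collinear_triple_reduces_to_one(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=(30, 1)).astype(np.int8)
        G = make_matrix(np.repeat(col, 3, axis=1))
        G2, _ = vif_prune(G, window=3, step=1, vif_threshold=2.0)
        assert G2.n_loci == 1

    def test_independent_snps_all_survive(self):
        G, _ = simulate_inbred_genotypes(
            SimulationConfig(n_individuals=400, n_loci=20, seed=6, f_model="constant",
                             maf_min=0.3)
        )
        G2, _ = vif_prune(G, window=10, step=2, vif_threshold=2.0)
        assert G2.n_loci >= 19  # true r2 = 0 everywhere; at most sampling noise

    def test_postcondition_no_window_above_threshold(self):
        rng = np.random.default_rng(7)
        base = rng.integers(0, 3, size=(60, 30)).astype(np.int8)
        # plant correlated runs
        for j in range(1, 30, 3):
            base[:, j] = base[:, j - 1]
        G = make_matrix(base)
        G2, _ = vif_prune(G, window=8, step=2, vif_threshold=2.0)
        x = G2.dosage_float()
        for start in range(0, G2.n_loci, 2):
            win = x[:, start : start + 8]
            if win.shape[1] > 1:
                assert _window_vifs(win).max() <= 2.0 + 1e-8

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        base = rng.integers(0, 3, size=(40, 20)).astype(np.int8)
        base[:, 5] = base[:, 4]
        G = make_matrix(base)
        G1, _ = vif_prune(G, window=6, step=2, vif_threshold=2.0)
        G2, _ = vif_prune(G1, window=6, step=2, vif_threshold=2.0)
        assert G1 == G2


class TestStageIdempotence:
    def test_locus_filters_idempotent(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(-1, 3, size=(30, 40)).astype(np.int8)
        G = make_matrix(calls)
        for stage, args in [
            (filter_maf, (0.1,)),
            (filter_call_rate, (0.7,)),
            (filter_hwe, (0.001,)),
            (drop_high_missing_individuals, (0.5,)),
        ]:
            G1, _ = stage(G, *args)
            G2, _ = stage(G1, *args)
            assert G1 == G2, stage.__name__


class TestCascade:
    def test_empty_matrix_all_cascades(self):
        G = make_matrix(np.empty((3, 0), dtype=np.int8))
        for which in "ABC":
            out, reports = cascade(G, which)
            assert out.n_loci == 0
            assert all(r.loci_after == 0 for r in reports)

    def test_cascade_counts_monotone_and_audit_consistent(self):
        parents, _ = simulate_inbred_genotypes(
            SimulationConfig(n_individuals=20, n_loci=120, seed=10, f_model="two_point")
        )
        G, ped, _ = simulate_trios(parents, 8, seed=11)
        G = __import__("radpop").apply_depth_and_missingness(
            G, SimulationConfig(seed=12, missing_rate=0.05, depth_mean=18)
        )
        idx = ScaffoldIndex({"scaf1": 10_000_000})
        out, reports = cascade(G, "A", ped=ped, idx=idx,
                               keep_list=parents.individual_ids)
        for prev, nxt in zip(reports, reports[1:]):
            assert nxt.loci_before == prev.loci_after
            assert nxt.individuals_before == prev.individuals_after
        assert all(r.loci_after <= r.loci_before for r in reports)
        assert out.n_loci == reports[-1].loci_after

    def test_cascade_c_runs_end_to_end(self):
        parents, _ = simulate_inbred_genotypes(
            SimulationConfig(n_individuals=16, n_loci=80, seed=13, f_model="two_point")
        )
        G, ped, _ = simulate_trios(parents, 6, seed=14)
        G = __import__("radpop").apply_depth_and_missingness(
            G, SimulationConfig(seed=15, missing_rate=0.02)
        )
        out, reports = cascade(G, "C", ped=ped)
        names = [r.stage_name for r in reports]
        assert names[0] == "drop_high_missing_individuals"
        assert "vif_prune" in names
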