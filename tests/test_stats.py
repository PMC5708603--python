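import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from pindiff import (
    activity_profiles,
    class_enrichment,
    delta_stat_correlation,
    driver_auc,
    elevated_stat_test,
    gene_tendencies,
    rank_auc,
    select_features,
)
from pindiff.calibration import AssignmentTensor
from pindiff.gainloss import FunctionDelta
from pindiff.io import GeneSetCollection

from test_gainloss import hypergeom_fisher_oracle, _rec


def ranksum_permutation_oracle(set_vals, rest_vals):
    """Exhaustive one-sided rank-sum permutation p (set > rest), exact under ties."""
    combined = np.concatenate([set_vals, rest_vals])
    ranks = sps.rankdata(combined)
    k = len(set_vals)
    observed = ranks[:k].sum()
    hits, total = 0, 0
    for idx in combinations(range(len(combined)), k):
        total += 1
        if ranks[list(idx)].sum() >= observed - 1e-12:
            hits += 1
    return hits / total


def auc_pair_counting_oracle(scores, labels):
    """AUC as the fraction of (positive, negative) pairs ranked correctly."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestElevatedStatTest:
    def test_extreme_separation_flags(self):
        rng = np.random.default_rng(0)
        set_vals = rng.uniform(0.5, 0.9, 10)
        rest = rng.uniform(0.0, 0.4, 100)
        p, flag = elevated_stat_test(set_vals, rest)
        assert flag == 1 and p < 1e-4

    def test_empty_set_is_flagged_null(self):
        p, flag = elevated_stat_test(np.array([]), np.array([0.1, 0.2]))
        assert (p, flag) == (1.0, 0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_permutation_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        # tie-heavy small-sample input
        set_vals = rng.choice([0.0, 0.1, 0.2], size=3)
        rest = rng.choice([0.0, 0.1, 0.2], size=5)
        p, _ = elevated_stat_test(set_vals, rest)
        assert p == pytest.approx(ranksum_permutation_oracle(set_vals, rest))

    def test_type_i_error_rate_near_nominal(self):
        # set drawn from the background: flag rate ~5% over simulated draws
        rng = np.random.default_rng(1)
        flags = 0
        n_sim = 400
        for _ in range(n_sim):
            vals = rng.uniform(0, 1, 40)
            p, flag = elevated_stat_test(vals[:8], vals[8:])
            flags += flag
        rate = flags / n_sim
        assert 0.02 <= rate <= 0.08


class TestClassEnrichment:
    def test_symmetric_table_is_null(self):
        or_, p = class_enrichment([[7, 7], [7, 7]])
        assert or_ == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_zero_cell_is_inf(self):
        or_, _ = class_enrichment([[5, 0], [3, 7]])
        assert or_ == math.inf

    @pytest.mark.parametrize("seed", range(6))
    def test_p_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 16, size=4)  # margins <= 30
        or_, p = class_enrichment(t.reshape(2, 2))
        assert p == pytest.approx(hypergeom_fisher_oracle(*map(int, t)), rel=1e-8)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            class_enrichment([[1, -1], [0, 2]])


class TestDeltaStatCorrelation:
    def test_perfectly_monotone_is_one(self):
        assert delta_stat_correlation([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        assert delta_stat_correlation([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_ties_match_average_rank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0])

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v), dtype=float)
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2
                i = j
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert delta_stat_correlation(x, y) == pytest.approx(expected)

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError, match="3"):
            delta_stat_correlation([1, 2], [2, 1])

    def test_accepts_function_delta_records(self):
        deltas = [
            FunctionDelta("f1", {"a"}, set(), 10),
            FunctionDelta("f2", {"a", "b"}, set(), 10),
            FunctionDelta("f3", set(), {"a", "b", "c"}, 10),
        ]
        stat = {"f1": 0.1, "f2": 0.2, "f3": -0.3}
        rho = delta_stat_correlation(deltas, stat)
        assert rho == pytest.approx(1.0)


class TestDriverAuc:
    def test_top_ranked_positives_give_auc_one(self):
        tend = {f"g{i}": i / 10 for i in range(10)}
        auc, p = driver_auc(tend, {"g9", "g8"}, n_perm=200, rng_seed=0)
        assert auc == 1.0
        assert p < 0.1

    def test_matches_pair_counting_oracle(self):
        scores = [0.1, 0.4, 0.4, 0.2, 0.9]
        labels = [False, True, False, False, True]
        tend = {f"g{i}": s for i, s in enumerate(scores)}
        auc, _ = driver_auc(tend, {"g1", "g4"}, n_perm=50, rng_seed=1)
        assert auc == pytest.approx(auc_pair_counting_oracle(scores, labels))

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(0, 1, 30)
        tend1 = {f"g{i}": s for i, s in enumerate(scores)}
        tend2 = {f"g{i}": math.exp(3 * s) for i, s in enumerate(scores)}
        pos = {f"g{i}" for i in [3, 7, 12, 25]}
        auc1, _ = driver_auc(tend1, pos, n_perm=10, rng_seed=3)
        auc2, _ = driver_auc(tend2, pos, n_perm=10, rng_seed=3)
        assert auc1 == pytest.approx(auc2)

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(4)
        tend = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(0, 1, 200))}
        aucs = []
        for s in range(20):
            pos = set(rng.choice(sorted(tend), size=20, replace=False))
            auc, _ = driver_auc(tend, pos, n_perm=10, rng_seed=s)
            aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_add_one_smoothed_p_never_zero(self):
        tend = {f"g{i}": i * 1.0 for i in range(12)}
        _, p = driver_auc(tend, {"g11"}, n_perm=100, rng_seed=5)
        assert p >= 1 / 101

    def test_degenerate_positive_set_rejected(self):
        tend = {"a": 1.0, "b": 2.0}
        with pytest.raises(ValueError):
            driver_auc(tend, set(), n_perm=10, rng_seed=0)
        with pytest.raises(ValueError):
            driver_auc(tend, {"a", "b"}, n_perm=10, rng_seed=0)


def _tensor():
    genes = ["g0", "g1", "g2", "g3"]
    functions = ["f0", "f1"]
    samples = ["s0", "s1", "s2"]
    expressed = np.ones((4, 3), dtype=bool)
    expressed[3, 2] = False
    data = np.zeros((4, 2, 3), dtype=bool)
    data[0, 0, 0] = data[1, 0, 0] = True  # f0 in s0: two genes
    data[0, 0, 1] = True                  # f0 in s1: one gene
    data[2, 1, 2] = True                  # f1 in s2: one gene
    return AssignmentTensor(genes, functions, samples, data, expressed)


class TestActivityProfiles:
    def test_counts_match_direct_tally(self):
        t = _tensor()
        coll = GeneSetCollection({"f0": {"g0", "g3"}, "f1": {"g2"}})
        prof = activity_profiles(t, coll)
        assert prof.x_diffusion.tolist() == [[2, 1, 0], [0, 0, 1]]
        # X' = expressed annotated genes: f0 has g0 (always) + g3 (not in s2)
        assert prof.x_annotation.tolist() == [[2, 2, 1], [1, 1, 1]]

    def test_no_assignments_give_zero_counts(self):
        t = _tensor()
        t.data[:] = False
        coll = GeneSetCollection({"f0": {"g0"}, "f1": {"g1"}})
        assert activity_profiles(t, coll).x_diffusion.sum() == 0

    def test_constant_annotation_profile_scales_to_zero(self):
        t = _tensor()
        coll = GeneSetCollection({"f0": {"g0"}, "f1": {"g1"}})
        prof = activity_profiles(t, coll)
        assert np.all(prof.x_annotation == 1)
        assert np.all(prof.scaled("annotation") == 0.0)

    def test_scaled_diffusion_zero_mean_unit_sd(self):
        t = _tensor()
        coll = GeneSetCollection({"f0": {"g0"}, "f1": {"g1"}})
        z = activity_profiles(t, coll).scaled("diffusion")
        for row in z:
            if row.any():
                assert abs(row.mean()) < 1e-12
                assert row.std() == pytest.approx(1.0)


class TestSelectFeatures:
    def _deltas(self, values):
        return [
            FunctionDelta(f"f{i:04d}", {f"g{j}" for j in range(v)} if v > 0 else set(),
                          {f"h{j}" for j in range(-v)} if v < 0 else set(), 10)
            for i, v in enumerate(values)
        ]

    def test_hundred_functions_k1_gives_two(self):
        deltas = self._deltas(list(range(-50, 50)))
        sel = select_features(deltas, k_percent=1)
        assert len(sel) == 2
        assert "f0099" in sel and "f0000" in sel

    def test_all_equal_breaks_ties_by_id(self):
        # degenerate all-tied case: top and bottom picks coincide on the
        # lowest IDs and the union deduplicates
        deltas = self._deltas([0] * 10)
        sel = select_features(deltas, k_percent=10)
        assert sel == ["f0000"]

    def test_1184_functions_k1_gives_24_features(self):
        deltas = self._deltas(list(range(1184)))
        assert len(select_features(deltas, k_percent=1)) == 24

    def test_annotation_control_mode_uses_logfc_magnitude(self):
        deltas = self._deltas([5, -5, 1, 0])
        logfc = {"f0000": 0.01, "f0001": -0.9, "f0002": 0.5, "f0003": float("nan")}
        sel = select_features(deltas, k_percent=25, mode="annotation", logfc=logfc)
        assert sel == ["f0001", "f0002"]


class TestGeneTendencies:
    def test_fractions_over_evaluated_functions(self):
        records = [
            _rec("g", "f1", "gain"),
            _rec("g", "f2", "loss"),
            _rec("g", "f3", "none"),
            _rec("g", "f4", "gain"),
        ]
        t = gene_tendencies(records)["g"]
        assert t.gain_tendency == pytest.approx(0.5)
        assert t.loss_tendency == pytest.approx(0.25)
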