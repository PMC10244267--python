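"""Welch contrasts, weight quartiles, and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cumrisk.compare import (
    GroupDef,
    assign_weight_quartiles,
    compare_groups,
    quartile_boundaries,
    welch_t_test,
)
from cumrisk.exposure import ExposureMatrix, Individual
from cumrisk.toxref import RPFTable


def _welch_t(a, b, axis=-1):
    """Hand-rolled Welch statistic (kept independent of the implementation)."""
    ma, mb = a.mean(axis=axis), b.mean(axis=axis)
    va = a.var(axis=axis, ddof=1) / a.shape[axis]
    vb = b.var(axis=axis, ddof=1) / b.shape[axis]
    return (ma - mb) / np.sqrt(va + vb)


def permutation_p(a, b, n_perm=100_000, seed=0):
    """Independent oracle: permutation distribution of the Welch statistic."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    t_obs = abs(_welch_t(np.asarray(a), np.asarray(b)))
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    t = _welch_t(perms[:, : len(a)], perms[:, len(a) :])
    return float(np.mean(np.abs(t) >= t_obs))


class TestWelch:
    def test_identical_samples(self):
        t, dof, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_symmetry(self):
        a, b = [1.0, 2.5, 3.0, 4.2], [2.0, 2.2, 5.1]
        assert welch_t_test(a, b)[2] == pytest.approx(welch_t_test(b, a)[2])
        assert welch_t_test(a, b)[0] == pytest.approx(-welch_t_test(b, a)[0])

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            welch_t_test([2.0, 2.0], [3.0, 3.0])

    def test_satterthwaite_dof(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 8.0, 2.0])
        b = np.array([2.0, 2.1, 2.2, 1.9, 2.05, 2.3])
        t, dof, p = welch_t_test(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        expected_dof = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        assert dof == pytest.approx(expected_dof)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), dof), rel=1e-9)

    def test_agrees_with_permutation_oracle_small_n(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, 6)
        b = rng.normal(0.8, 1.0, 6)
        p_welch = welch_t_test(a, b)[2]
        p_perm = permutation_p(a, b, n_perm=100_000, seed=1)
        assert p_welch == pytest.approx(p_perm, abs=0.05)

    def test_p_uniform_under_null(self):
        """Kolmogorov check on the p-value distribution over replicates
        drawn from one common distribution."""
        rng = np.random.default_rng(11)
        pvals = [
            welch_t_test(rng.normal(size=30), rng.normal(size=30))[2] for _ in range(500)
        ]
        ks_p = stats.kstest(pvals, "uniform").pvalue
        assert ks_p > 1e-3

    def test_power_at_one_sd_shift(self):
        rng = np.random.default_rng(12)
        hits = sum(
            welch_t_test(rng.normal(0, 1, 200), rng.normal(1, 1, 200))[2] < 1e-3
            for _ in range(50)
        )
        assert hits >= 0.95 * 50


def make_individuals(weights, gender="female"):
    return [Individual(f"I{i}", 40, gender, w) for i, w in enumerate(weights)]


class TestQuartiles:
    def test_sort_and_split_oracle(self):
        inds = make_individuals([1, 2, 3, 4, 5, 6, 7, 8])
        q = assign_weight_quartiles(inds)
        assert {i for i, v in q.items() if v == "Q1"} == {"I0", "I1"}
        assert {i for i, v in q.items() if v == "Q4"} == {"I6", "I7"}

    def test_degenerate_all_equal(self):
        inds = make_individuals([70.0] * 6)
        with pytest.warns(UserWarning):
            q = assign_weight_quartiles(inds)
        assert set(q.values()) == {"Q1"}

    def test_fewer_than_four_rejected(self):
        with pytest.raises(ValueError):
            assign_weight_quartiles(make_individuals([60, 70, 80]))

    def test_quartiles_hold_quarter_each(self):
        rng = np.random.default_rng(2)
        inds = make_individuals(rng.normal(75, 12, 200).clip(40))
        q = assign_weight_quartiles(inds)
        counts = pd.Series(list(q.values())).value_counts()
        for label in ["Q1", "Q2", "Q3", "Q4"]:
            assert abs(counts[label] - 50) <= 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        weights = list(rng.normal(75, 10, 40))
        inds = make_individuals(weights)
        shuffled = list(inds)
        rng.shuffle(shuffled)
        assert assign_weight_quartiles(inds) == assign_weight_quartiles(shuffled)

    def test_boundary_goes_to_lower_quartile(self):
        inds = make_individuals([1, 2, 3, 4, 5])  # q1 = 2.0 exactly
        q1, _, _ = quartile_boundaries(inds)
        q = assign_weight_quartiles(inds)
        assert q1 == 2.0 and q["I1"] == "Q1"


def matrix_from_days(values_by_id):
    """Single-chemical matrix: {id: [day1, day2]} -> ExposureMatrix."""
    rows, index = [], []
    for ind, days in values_by_id.items():
        for d, v in enumerate(days, start=1):
            rows.append(v)
            index.append((ind, d))
    df = pd.DataFrame(
        {"Pb": rows}, index=pd.MultiIndex.from_tuples(index, names=["individual", "day"])
    )
    return ExposureMatrix.from_entries(df)


RPF = RPFTable("neuro", "Pb", {"Pb": 1.0})
ENDPOINTS = {"neuro": (RPF, {"Pb": 0.05})}


class TestCompareGroups:
    def make(self, rng, n=20, shift=0.0):
        values = {
            f"A{i}": list(np.exp(rng.normal(np.log(0.1) + shift, 0.4, 2))) for i in range(n)
        } | {f"B{i}": list(np.exp(rng.normal(np.log(0.1), 0.4, 2))) for i in range(n)}
        matrix = matrix_from_days(values)
        ga = GroupDef("A", frozenset(k for k in values if k.startswith("A")))
        gb = GroupDef("B", frozenset(k for k in values if k.startswith("B")))
        return matrix, ga, gb

    def test_day_level_observations_count(self):
        matrix, ga, gb = self.make(np.random.default_rng(0), n=15)
        (res,) = compare_groups(matrix, [(ga, gb)], ENDPOINTS, "day")
        assert res.n_a == 30 and res.n_b == 30
        (res_i,) = compare_groups(matrix, [(ga, gb)], ENDPOINTS, "individual")
        assert res_i.n_a == 15

    def test_hi_is_mean_over_index_hbgv(self):
        matrix, ga, gb = self.make(np.random.default_rng(1))
        (res,) = compare_groups(matrix, [(ga, gb)], ENDPOINTS)
        assert res.hi_a == pytest.approx(res.mean_a / 0.05, rel=1e-9)

    def test_self_comparison_is_identity(self):
        matrix, ga, _ = self.make(np.random.default_rng(2))
        (res,) = compare_groups(matrix, [(ga, ga)], ENDPOINTS)
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_partial_overlap_rejected(self):
        matrix, ga, gb = self.make(np.random.default_rng(3))
        overlapping = GroupDef("C", frozenset(list(ga.ids) + list(gb.ids)[:2]))
        with pytest.raises(ValueError, match="overlap"):
            compare_groups(matrix, [(overlapping, gb)], ENDPOINTS)

    def test_empty_group_rejected(self):
        matrix, ga, _ = self.make(np.random.default_rng(4))
        with pytest.raises(ValueError, match="empty"):
            compare_groups(matrix, [(ga, GroupDef("E", frozenset()))], ENDPOINTS)

    def test_null_p_uniform_over_replicates(self):
        rng = np.random.default_rng(21)
        pvals = []
        for _ in range(200):
            matrix, ga, gb = self.make(rng, n=15)
            (res,) = compare_groups(matrix, [(ga, gb)], ENDPOINTS)
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_injected_shift_detected(self):
        rng = np.random.default_rng(22)
        hits = 0
        for _ in range(20):
            matrix, ga, gb = self.make(rng, n=100, shift=0.4)  # 1 within-group SD on log scale
            (res,) = compare_groups(matrix, [(ga, gb)], ENDPOINTS)
            hits += res.p_value < 1e-3
        assert hits >= 19
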