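import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metabscreen.feature_table import Label
from metabscreen.preprocessing import preprocess
from metabscreen.synthetic import SyntheticConfig, generate_dataset
from metabscreen.univariate import test_feature as compare_groups
from metabscreen.univariate import (
    intersect_cohorts,
    normality_gate,
    roc_auc,
    screen,
    storey_qvalues,
)
from conftest import make_table


# ---------------------------------------------------------------- oracles ---
def brute_force_qvalues(p, lambda_=0.5):
    """Direct evaluation of the min-over-tail q-value definition."""
    p = np.asarray(p, float)
    m = len(p)
    pi0 = min(1.0, np.mean(p > lambda_) / (1 - lambda_))
    if pi0 == 0:
        pi0 = 1.0 / m
    ranks = {}
    for i, pi in enumerate(p):
        ranks[i] = np.sum(p <= pi)  # max rank under ties
    q = np.empty(m)
    for i, pi in enumerate(p):
        tail = [pi0 * m * pj / ranks[j] for j, pj in enumerate(p) if pj >= pi]
        q[i] = min(1.0, min(tail))
    return q


def brute_force_auc(values, is_case):
    """Pair counting with half-credit for ties."""
    pos = values[is_case]
    neg = values[~is_case]
    wins = sum((pv > nv) + 0.5 * (pv == nv) for pv in pos for nv in neg)
    return wins / (len(pos) * len(neg))


def exact_mw_p(case, control):
    """Two-sided Mann-Whitney p by full enumeration of labelings."""
    pooled = np.concatenate([case, control])
    n1 = len(case)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(control) / 2
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


# ----------------------------------------------------------------- gating ---
class TestNormalityGate:
    def test_normal_data_acceptance_rate(self):
        """Both groups N(0,1), n=50: joint pass rate ~0.9*0.9 = 0.81 +- 0.05."""
        rng = np.random.default_rng(0)
        passes = sum(
            normality_gate(rng.normal(size=50), rng.normal(size=50)) for _ in range(600)
        )
        assert abs(passes / 600 - 0.81) < 0.05

    def test_bimodal_rejected(self):
        rng = np.random.default_rng(1)
        rejected = 0
        for _ in range(100):
            bimodal = np.concatenate(
                [rng.normal(-5, 0.1, 25), rng.normal(5, 0.1, 25)]
            )
            rejected += not normality_gate(bimodal, rng.normal(size=50))
        assert rejected >= 99

    def test_constant_group_fails_gate(self):
        assert not normality_gate(np.full(5, 3.0), np.random.default_rng(0).normal(size=5))

    def test_needs_three_per_group(self):
        with pytest.raises(ValueError):
            normality_gate(np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]))


# ------------------------------------------------------------------ tests ---
class TestTestFeature:
    def test_identical_samples_p_one(self):
        _, mw_p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], gate=False)
        assert mw_p == pytest.approx(1.0)

    def test_exact_four_vs_four(self):
        """Fully separated 4v4: exact two-sided p = 2/70 by enumeration."""
        case = np.array([10.0, 11.0, 12.0, 13.0])
        control = np.array([1.0, 2.0, 3.0, 4.0])
        _, mw_p = compare_groups(case, control, gate=False)
        assert mw_p == pytest.approx(2 / 70, rel=1e-10)
        assert mw_p == pytest.approx(exact_mw_p(case, control), rel=1e-10)

    def test_exact_matches_enumeration_random(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            case = rng.normal(size=5)
            control = rng.normal(size=4)
            _, mw_p = compare_groups(case, control, gate=False)
            assert mw_p == pytest.approx(exact_mw_p(case, control), rel=1e-9)

    def test_location_invariance(self):
        rng = np.random.default_rng(2)
        case, control = rng.normal(size=30), rng.normal(size=30)
        t1, m1 = compare_groups(case, control, gate=True)
        t2, m2 = compare_groups(case + 100.0, control + 100.0, gate=True)
        assert t1 == pytest.approx(t2) and m1 == pytest.approx(m2)

    def test_gate_controls_t_presence(self):
        case, control = np.arange(10.0), np.arange(10.0) + 1
        assert compare_groups(case, control, gate=False)[0] is None
        assert compare_groups(case, control, gate=True)[0] is not None


# ----------------------------------------------------------------- storey ---
class TestStoreyQ:
    def test_single_max_p(self):
        assert storey_qvalues(np.array([1.0]))[0] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            m = rng.integers(1, 21)
            p = rng.random(m)
            np.testing.assert_allclose(storey_qvalues(p), brute_force_qvalues(p), rtol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_property_monotone_and_bounded(self, pvals):
        p = np.array(pvals)
        q = storey_qvalues(p)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in p

    def test_order_invariance(self):
        p = np.random.default_rng(5).random(15)
        perm = np.random.default_rng(6).permutation(15)
        np.testing.assert_allclose(storey_qvalues(p)[perm], storey_qvalues(p[perm]))

    def test_null_pi0_near_one(self):
        rng = np.random.default_rng(7)
        pi0s = []
        for _ in range(100):
            p = rng.random(1000)
            pi0s.append(min(1.0, np.mean(p > 0.5) / 0.5))
        assert 0.9 < np.mean(pi0s) <= 1.0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.5, 1.5]))


# -------------------------------------------------------------------- auc ---
class TestAUC:
    def test_perfect_separation(self):
        auc, lo, hi = roc_auc(np.array([1.0, 2.0]), np.array([False, True]))
        assert auc == 1.0

    def test_complete_tie(self):
        auc, _, _ = roc_auc(np.array([5.0, 5.0]), np.array([False, True]))
        assert auc == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = rng.integers(4, 15)
            v = rng.integers(0, 5, size=n).astype(float)  # force ties
            y = np.zeros(n, bool)
            y[rng.choice(n, size=rng.integers(1, n), replace=False)] = True
            if y.all() or not y.any():
                continue
            auc, lo, hi = roc_auc(v, y)
            assert auc == pytest.approx(brute_force_auc(v, y), rel=1e-12)
            assert 0 <= lo <= auc <= hi <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2.0]), np.array([True, True]))


# ------------------------------------------------------------------ screen --
def _screen_table(seed, effect, n_case=25, n_ctrl=25, m=200, planted=0):
    cfg = SyntheticConfig(
        n_cases=n_case, n_controls=n_ctrl, n_qc=6, n_blank=4, n_features=m,
        n_discriminative=planted, effect_size=effect, seed=seed,
    )
    table, truth = generate_dataset(cfg)
    clean, _ = preprocess(table, rng=seed)
    return clean, truth


class TestScreen:
    def test_row_count_matches_features(self):
        clean, _ = _screen_table(seed=0, effect=0.0, m=50)
        res = screen(clean)
        assert len(res.table) == clean.n_features

    def test_null_median_mw_selection_zero(self):
        """Null data: the median number of MW-selected features is 0."""
        counts = []
        for seed in range(50):
            clean, _ = _screen_table(seed=seed, effect=0.0, m=100)
            counts.append(int(screen(clean).table["selected_mw"].sum()))
        assert np.median(counts) == 0

    def test_planted_power(self):
        """>=80% of planted features (delta=1.5) appear in the MW selection."""
        rates = []
        for seed in range(20):
            clean, truth = _screen_table(
                seed=seed, effect=1.5, n_case=20, n_ctrl=151, m=150, planted=15
            )
            res = screen(clean)
            hits = set(res.table.index[res.table["selected_mw"]]) & truth.discriminative_names
            rates.append(len(hits) / len(truth.discriminative_names))
        assert np.mean(rates) >= 0.8

    def test_selected_both_implies_both_families(self):
        clean, _ = _screen_table(seed=1, effect=1.5, planted=20)
        res = screen(clean).table
        both = res["selected_both"]
        assert (res.loc[both, "selected_t"]).all()
        assert (res.loc[both, "selected_mw"]).all()
        assert not res.loc[~res["normality_gate"], "selected_both"].any()

    def test_empirical_fdr_bounded(self):
        """FDR among MW q<0.15 selections stays <= 0.25 with 10% true effects."""
        v, r = 0, 0
        for seed in range(40):
            clean, truth = _screen_table(
                seed=100 + seed, effect=2.0, n_case=30, n_ctrl=30, m=100, planted=10
            )
            res = screen(clean).table
            sel = set(res.index[res["selected_mw"]])
            r += len(sel)
            v += len(sel - truth.discriminative_names)
        assert r > 0  # effects this large must be found sometimes
        assert v / r <= 0.25


class TestIntersect:
    def _fake_result(self, names, selected):
        import pandas as pd
        from metabscreen.univariate import UnivariateScreenResult

        df = pd.DataFrame(
            {
                "direction": "case_up",
                "t_p": 0.001,
                "mw_p": 0.002,
                "selected_both": [n in selected for n in names],
            },
            index=pd.Index(names, name="feature"),
        )
        return UnivariateScreenResult(table=df, q_threshold=0.15)

    def test_identical_selection(self):
        a = self._fake_result(["1.00_100.0000m/z", "2.00_200.0000n"], {"1.00_100.0000m/z"})
        out = intersect_cohorts(a, a)
        assert list(out["feature_a"]) == ["1.00_100.0000m/z"]

    def test_disjoint_empty(self):
        a = self._fake_result(["1.00_100.0000m/z"], {"1.00_100.0000m/z"})
        b = self._fake_result(["2.00_200.0000n"], {"2.00_200.0000n"})
        assert intersect_cohorts(a, b).empty

    def test_partial_overlap(self):
        names = ["1.00_100.0000m/z", "2.00_200.0000n", "3.00_300.0000m/z"]
        a = self._fake_result(names, {names[0], names[1]})
        b = self._fake_result(names, {names[1], names[2]})
        out = intersect_cohorts(a, b)
        assert list(out["feature_a"]) == [names[1]]

    def test_tolerance_matching(self):
        a = self._fake_result(["1.00_100.0000m/z"], {"1.00_100.0000m/z"})
        b = self._fake_result(["1.01_100.0002m/z"], {"1.01_100.0002m/z"})
        out = intersect_cohorts(a, b, rt_tol=0.02, mass_ppm_tol=5.0)
        assert len(out) == 1
        assert intersect_cohorts(a, b).empty  # exact matching misses it

    def test_ambiguous_tolerance_raises(self):
        a = self._fake_result(["1.00_100.0000m/z"], {"1.00_100.0000m/z"})
        b = self._fake_result(
            ["1.01_100.0001m/z", "1.00_100.0002m/z"],
            {"1.01_100.0001m/z", "1.00_100.0002m/z"},
        )
        with pytest.raises(ValueError, match="ambiguous"):
            intersect_cohorts(a, b, rt_tol=0.02, mass_ppm_tol=5.0)
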