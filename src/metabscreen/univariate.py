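"""Per-feature two-group screening with normality gating, Storey FDR, and ROC.

Each feature is tested case-vs-control: a Welch t-test where the Shapiro-Wilk
test accepts normality in both groups (p > 0.10), and a two-sided
Mann-Whitney test always.  False discovery rates follow Storey's q-value with
a fixed-lambda pi0 estimate, computed separately within each test family
(the t family over gated features only, the Mann-Whitney family over all
features).  Discrimination strength is summarized by the rank-based AUC with
a Hanley-McNeil 95% confidence interval.  Features with q < 0.15 in both
families form the reported selection, sorted by ascending t-test p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .feature_table import FeatureTable

__all__ = [
    "normality_gate",
    "test_feature",
    "storey_qvalues",
    "roc_auc",
    "screen",
    "intersect_cohorts",
    "UnivariateScreenResult",
]


def normality_gate(
    values_case: np.ndarray, values_control: np.ndarray, p_threshold: float = 0.10
) -> bool:
    """True iff Shapiro-Wilk accepts normality (p > threshold) in BOTH groups.

    Constant vectors fail the gate by convention (normality untestable).
    """
    for v in (values_case, values_control):
        v = np.asarray(v, dtype=float)
        if len(v) < 3:
            raise ValueError("normality_gate needs >= 3 values per group")
        if np.ptp(v) == 0:
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if stats.shapiro(v).pvalue <= p_threshold:
                return False
    return True


def test_feature(
    values_case: np.ndarray,
    values_control: np.ndarray,
    gate: bool | None = None,
    p_threshold: float = 0.10,
    equal_var: bool = False,
) -> tuple[float | None, float]:
    """Welch t-test p-value (when the normality gate passes) and the two-sided
    Mann-Whitney p-value (always, exact for small tie-free groups, tie-corrected
    normal approximation otherwise)."""
    vc = np.asarray(values_case, dtype=float)
    vn = np.asarray(values_control, dtype=float)
    if len(vc) < 2 or len(vn) < 2:
        raise ValueError("test_feature needs >= 2 values per group")
    if gate is None:
        gate = normality_gate(vc, vn, p_threshold) if min(len(vc), len(vn)) >= 3 else False
    t_p = float(stats.ttest_ind(vc, vn, equal_var=equal_var).pvalue) if gate else None
    pooled = np.concatenate([vc, vn])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(vc), len(vn)) <= 8 and not has_ties) else "asymptotic"
    mw_p = float(
        stats.mannwhitneyu(vc, vn, alternative="two-sided", method=method).pvalue
    )
    return t_p, min(mw_p, 1.0)


def storey_qvalues(pvalues: np.ndarray, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values with the fixed-lambda pi0 estimate.

    pi0 = #{p > lambda} / (m (1 - lambda)), capped at 1; the q-value of p_(i)
    is min over the tail p_(j) >= p_(i) of pi0 * m * p_(j) / rank(j).  Output
    order matches input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a nonempty 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if not 0 <= lambda_ < 1:
        raise ValueError("lambda_ must be in [0, 1)")
    pi0 = min(1.0, np.mean(p > lambda_) / (1.0 - lambda_)) if m else 1.0
    if pi0 == 0.0:
        pi0 = 1.0 / m  # degenerate: every p below lambda; keep q well-defined
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def roc_auc(values: np.ndarray, is_case: np.ndarray) -> tuple[float, float, float]:
    """Rank-based AUC (case positive, half-credit for ties) with the
    Hanley-McNeil 95% confidence interval, clipped to [0, 1]."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(is_case, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = stats.rankdata(v)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a**2 / (1 + a)
    se2 = (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n0 - 1) * (q2 - a**2)) / (n1 * n0)
    half = 1.959963984540054 * np.sqrt(max(se2, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


@dataclass
class UnivariateScreenResult:
    """Per-feature statistics plus the doubly-selected subset (q < threshold
    in both the t and Mann-Whitney families), ordered by ascending t_p."""

    table: pd.DataFrame
    q_threshold: float

    @property
    def selected_both(self) -> pd.DataFrame:
        sel = self.table[self.table["selected_both"]]
        return sel.sort_values("t_p", kind="stable")

    @property
    def selected_mw(self) -> pd.DataFrame:
        return self.table[self.table["selected_mw"]]


def screen(
    table: FeatureTable,
    q_threshold: float = 0.15,
    shapiro_threshold: float = 0.10,
    lambda_: float = 0.5,
    equal_var: bool = False,
) -> UnivariateScreenResult:
    """Run the full univariate screen on a preprocessed study matrix."""
    case = table.case_mask
    ctrl = table.control_mask
    if case.sum() < 3 or ctrl.sum() < 3:
        raise ValueError("screen requires >= 3 samples per outcome group")
    x = table.intensities
    rows = []
    for j, name in enumerate(table.feature_names):
        vc, vn = x[case, j], x[ctrl, j]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sh_c = float(stats.shapiro(vc).pvalue) if np.ptp(vc) > 0 else 0.0
            sh_n = float(stats.shapiro(vn).pvalue) if np.ptp(vn) > 0 else 0.0
        gate = sh_c > shapiro_threshold and sh_n > shapiro_threshold
        t_p, mw_p = test_feature(vc, vn, gate=gate, equal_var=equal_var)
        auc, lo, hi = roc_auc(x[case | ctrl, j], case[case | ctrl])
        rows.append(
            {
                "feature": name,
                "shapiro_p_case": sh_c,
                "shapiro_p_control": sh_n,
                "normality_gate": gate,
                "direction": "case_up" if vc.mean() > vn.mean() else "control_up",
                "t_p": t_p if t_p is not None else np.nan,
                "mw_p": mw_p,
                "auc": auc,
                "auc_ci_low": lo,
                "auc_ci_high": hi,
                "auc_significant": lo > 0.5 or hi < 0.5,
            }
        )
    res = pd.DataFrame(rows).set_index("feature")
    res["mw_q"] = storey_qvalues(res["mw_p"].to_numpy(), lambda_=lambda_)
    res["t_q"] = np.nan
    gated = res["normality_gate"].to_numpy()
    if gated.any():
        res.loc[gated, "t_q"] = storey_qvalues(res.loc[gated, "t_p"].to_numpy(), lambda_=lambda_)
    res["selected_t"] = gated & (res["t_q"] < q_threshold)
    res["selected_mw"] = res["mw_q"] < q_threshold
    res["selected_both"] = res["selected_t"] & res["selected_mw"]
    return UnivariateScreenResult(table=res, q_threshold=q_threshold)


def intersect_cohorts(
    results_a: UnivariateScreenResult,
    results_b: UnivariateScreenResult,
    selection: str = "selected_both",
    rt_tol: float | None = None,
    mass_ppm_tol: float | None = None,
) -> pd.DataFrame:
    """Features selected in both cohorts, matched by exact formatted id
    (default) or by retention-time / mass tolerance when both are given.

    Returns one row per match with both cohorts' p-values.  Ambiguous
    many-to-many tolerance matches raise, listing the offenders.
    """
    sel_a = results_a.table[results_a.table[selection]]
    sel_b = results_b.table[results_b.table[selection]]
    pairs: list[tuple[str, str]] = []
    if rt_tol is None and mass_ppm_tol is None:
        common = [f for f in sel_a.index if f in set(sel_b.index)]
        pairs = [(f, f) for f in common]
    else:
        from .feature_table import parse_feature_id

        rt_tol = rt_tol if rt_tol is not None else 0.02
        mass_ppm_tol = mass_ppm_tol if mass_ppm_tol is not None else 5.0
        ids_b = {name: parse_feature_id(name) for name in sel_b.index}
        used_b: dict[str, str] = {}
        for name_a in sel_a.index:
            fa = parse_feature_id(name_a)
            hits = [
                nb
                for nb, fb in ids_b.items()
                if fb.mass_kind == fa.mass_kind
                and abs(fb.rt - fa.rt) <= rt_tol
                and abs(fb.mass - fa.mass) <= mass_ppm_tol * 1e-6 * fa.mass
            ]
            if len(hits) > 1:
                raise ValueError(f"ambiguous tolerance match for {name_a}: {sorted(hits)}")
            if hits:
                nb = hits[0]
                if nb in used_b:
                    raise ValueError(
                        f"ambiguous tolerance match: {used_b[nb]} and {name_a} both match {nb}"
                    )
                used_b[nb] = name_a
                pairs.append((name_a, nb))
    rows = [
        {
            "feature_a": fa,
            "feature_b": fb,
            "direction": sel_a.loc[fa, "direction"],
            "t_p_a": sel_a.loc[fa, "t_p"],
            "mw_p_a": sel_a.loc[fa, "mw_p"],
            "t_p_b": sel_b.loc[fb, "t_p"],
            "mw_p_b": sel_b.loc[fb, "mw_p"],
        }
        for fa, fb in pairs
    ]
    return pd.DataFrame(
        rows, columns=["feature_a", "feature_b", "direction", "t_p_a", "mw_p_a", "t_p_b", "mw_p_b"]
    )
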