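"""Feature-table pre-treatment: QC/blank filtering, low-value imputation,
probabilistic quotient normalization, sqrt transform, mean centering, Pareto
scaling, and a PCA-based outlier screen.

The composite :func:`preprocess` applies the stages in the one order the
analysis is defined for::

    filter -> impute -> PQN -> sqrt -> center -> Pareto

Filtering keeps a feature when it is essentially absent from solvent blanks
(more than 95% missing in blanks) OR clearly above blank background (5th
percentile in QCs / 95th percentile in blanks > 5), and then drops features
whose QC coefficient of variation exceeds 20% — i.e. features the platform
does not measure reproducibly.  The CV is computed on raw, pre-normalization
QC intensities with the sample (n-1) SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .feature_table import FeatureTable, Role

__all__ = [
    "FilterConfig",
    "FilterReport",
    "OutlierReport",
    "PreprocessReport",
    "filter_features",
    "impute_missing",
    "pqn_normalize",
    "transform_scale",
    "detect_outliers_pca",
    "preprocess",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    blank_missing_min: float = 0.95  # keep if frac missing in blanks exceeds this
    qc_blank_ratio_min: float = 5.0  # or if QC q05 / blank q95 exceeds this
    qc_cv_max: float = 0.20  # then drop if QC CV exceeds this
    require_blanks: bool = True  # waive blank criteria when no blanks present


@dataclass
class FilterReport:
    """Per-feature filter flags plus retained/removed counts at each step."""

    flags: pd.DataFrame  # included_by_blank_missingness / included_by_qc_blank_ratio / excluded_by_qc_cv / retained
    n_input: int
    n_after_blank_rules: int
    n_retained: int

    @property
    def retained_mask(self) -> np.ndarray:
        return self.flags["retained"].to_numpy()


@dataclass
class OutlierReport:
    """Hotelling T2 and DModX statistics per study sample, per outcome group."""

    table: pd.DataFrame  # sample_id, group, t2, t2_crit, t2_flag, dmodx, dmodx_crit, dmodx_flag
    alpha: float

    @property
    def any_flagged(self) -> bool:
        return bool((self.table["t2_flag"] | self.table["dmodx_flag"]).any())


@dataclass
class PreprocessReport:
    filter_report: FilterReport
    quotients: pd.Series  # per-sample PQN quotients
    degenerate_features: list[str]  # zero-variance columns left as zeros
    outlier_report: OutlierReport | None = None


def filter_features(
    table: FeatureTable, config: FilterConfig = FilterConfig()
) -> tuple[FeatureTable, FilterReport]:
    """Apply the blank/QC inclusion rules and the QC-CV exclusion rule.

    Returns the filtered table restricted to study samples (QC and blank rows
    have served their purpose) together with a per-feature report.
    Percentiles use linear-interpolation (type-7) quantiles over present
    values.  Features with fewer than two present QC values cannot demonstrate
    reproducibility and are excluded by the CV rule.
    """
    qc = table.role_mask(Role.QC)
    blank = table.role_mask(Role.BLANK)
    if qc.sum() < 1:
        raise ValueError("filter_features requires at least one QC sample (CV undefined)")
    if blank.sum() < 1 and config.require_blanks:
        raise ValueError(
            "filter_features requires blank samples (set require_blanks=False to waive)"
        )
    x = table.intensities
    xq = x[qc]
    xb = x[blank] if blank.sum() else np.empty((0, table.n_features))

    p = table.n_features
    inc_blank = np.zeros(p, dtype=bool)
    inc_ratio = np.zeros(p, dtype=bool)
    exc_cv = np.zeros(p, dtype=bool)
    for j in range(p):
        bj = xb[:, j]
        qj = xq[:, j][np.isfinite(xq[:, j])]
        if len(bj):
            frac_missing = np.mean(~np.isfinite(bj))
            inc_blank[j] = frac_missing > config.blank_missing_min
            bj_present = bj[np.isfinite(bj)]
            if len(bj_present) and len(qj):
                b95 = np.quantile(bj_present, 0.95)
                q05 = np.quantile(qj, 0.05)
                ratio = np.inf if b95 == 0 else q05 / b95
                inc_ratio[j] = ratio > config.qc_blank_ratio_min
            # all blank values missing: already included by the first rule;
            # ratio left unevaluated (avoids 0-division)
        else:
            inc_blank[j] = True  # blank criteria waived
        if len(qj) < 2:
            exc_cv[j] = True
        else:
            m = qj.mean()
            exc_cv[j] = m == 0 or qj.std(ddof=1) / m > config.qc_cv_max
    retained = (inc_blank | inc_ratio) & ~exc_cv

    flags = pd.DataFrame(
        {
            "included_by_blank_missingness": inc_blank,
            "included_by_qc_blank_ratio": inc_ratio,
            "excluded_by_qc_cv": exc_cv,
            "retained": retained,
        },
        index=table.feature_names,
    )
    report = FilterReport(
        flags=flags,
        n_input=p,
        n_after_blank_rules=int((inc_blank | inc_ratio).sum()),
        n_retained=int(retained.sum()),
    )
    out = table.subset_features(retained).subset_samples(table.study_mask)
    return out, report


def impute_missing(
    table: FeatureTable,
    rng: np.random.Generator | int | None = 0,
    drop_all_missing: bool = False,
) -> FeatureTable:
    """Replace each missing entry by an independent uniform draw on
    (0, min_j), where min_j is the feature's smallest present intensity.

    Deterministic given the rng seed.  A feature with no present value has no
    defined minimum; pass ``drop_all_missing=True`` to drop such features,
    otherwise they raise.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = table.intensities.copy()
    all_missing = ~np.isfinite(x).any(axis=0)
    if all_missing.any():
        bad = [n for n, b in zip(table.feature_names, all_missing) if b]
        if not drop_all_missing:
            raise ValueError(
                f"{len(bad)} feature(s) have no present values (e.g. {bad[:3]}); "
                "drop them first (drop_all_missing=True)"
            )
        table = table.subset_features(~all_missing)
        x = table.intensities.copy()
    mins = np.nanmin(x, axis=0)
    missing = ~np.isfinite(x)
    if missing.any():
        # one draw per missing cell, row-major order for reproducibility
        u = rng.random(size=int(missing.sum()))
        rows, cols = np.nonzero(missing)
        x[rows, cols] = u * mins[cols]
    return table.with_intensities(x)


def pqn_normalize(
    table: FeatureTable,
    reference: np.ndarray | str = "auto",
    qc_table: FeatureTable | None = None,
) -> tuple[FeatureTable, pd.Series]:
    """Probabilistic quotient normalization against a median reference spectrum.

    ``reference`` may be an explicit spectrum, ``"study"`` (median over the
    table's study rows), ``"qc"`` (median over ``qc_table`` rows, which must
    then be supplied), or ``"auto"``: QC median when at least 3 QC spectra are
    available, else study median.  Each sample is divided by the median of its
    feature-wise ratios to the reference; quotients are returned for audit.
    """
    x = table.intensities
    if not np.all(np.isfinite(x) & (x > 0)):
        raise ValueError("pqn_normalize requires a fully imputed, strictly positive matrix")
    if isinstance(reference, str):
        n_qc = 0 if qc_table is None else qc_table.n_samples
        if reference == "qc" or (reference == "auto" and n_qc >= 3):
            if qc_table is None:
                raise ValueError("reference='qc' requires qc_table")
            r = np.nanmedian(qc_table.intensities, axis=0)
        elif reference in ("study", "auto"):
            r = np.median(x[table.study_mask] if table.study_mask.any() else x, axis=0)
        else:
            raise ValueError(f"unknown reference policy {reference!r}")
    else:
        r = np.asarray(reference, dtype=float)
    if r.shape != (table.n_features,):
        raise ValueError("reference spectrum length does not match feature count")
    if np.any(~np.isfinite(r)) or np.any(r == 0):
        raise ValueError("reference spectrum contains zeros or non-finite values")
    q = np.median(x / r[None, :], axis=1)
    if np.any(q <= 0):
        raise ValueError("non-positive PQN quotient encountered")
    out = table.with_intensities(x / q[:, None])
    return out, pd.Series(q, index=table.sample_ids, name="pqn_quotient")


def transform_scale(table: FeatureTable) -> tuple[FeatureTable, list[str]]:
    """Square-root transform, mean-center, and Pareto-scale each feature.

    Pareto scaling divides the centered column by the square root of its
    sample SD, damping but not removing scale differences.  Constant columns
    are left as all-zeros and returned as flagged feature names.
    """
    x = table.intensities
    if np.nanmin(x, initial=0.0) < 0:
        raise ValueError("transform_scale requires nonnegative intensities")
    y = np.sqrt(x)
    y = y - y.mean(axis=0)
    sd = y.std(axis=0, ddof=1) if table.n_samples > 1 else np.zeros(table.n_features)
    degenerate = sd == 0
    scale = np.where(degenerate, 1.0, np.sqrt(np.where(degenerate, 1.0, sd)))
    y = np.where(degenerate[None, :], 0.0, y / scale[None, :])
    flagged = [n for n, d in zip(table.feature_names, degenerate) if d]
    if flagged:
        log.info("transform_scale: %d constant feature(s) left as zeros", len(flagged))
    return table.with_intensities(y, allow_negative=True), flagged


def _hotelling_crit(n: int, a: int, alpha: float) -> float:
    # in-model limit: for a training sample, T2 / (n-1)^2 * n ~ Beta(a/2, (n-a-1)/2)
    return (n - 1) ** 2 / n * stats.beta.ppf(1 - alpha, a / 2, (n - a - 1) / 2)


def detect_outliers_pca(table: FeatureTable, alpha: float = 0.05) -> OutlierReport:
    """PCA outlier screen per outcome group: Hotelling T2 on the scores and
    DModX on the orthogonal residuals, both against F critical values.

    The component count per group is the smallest capturing >= 80% of the
    variance, capped at min(n-1, 10).  Samples are flagged, never removed.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rows = []
    for group, mask in (("case", table.case_mask), ("control", table.control_mask)):
        if not mask.any():
            continue
        n = int(mask.sum())
        if n < 3:
            raise ValueError(f"group {group!r} has {n} samples; need >= 3 for the PCA screen")
        ids = [s for s, m in zip(table.sample_ids, mask) if m]
        x = table.intensities[mask]
        xc = x - x.mean(axis=0)
        u, sv, vt = np.linalg.svd(xc, full_matrices=False)
        var = sv**2
        var = var[var > 1e-12 * var.max()] if var.max() > 0 else var
        cum = np.cumsum(var) / var.sum()
        a = int(np.searchsorted(cum, 0.80) + 1)
        a = min(a, n - 1, 10, len(var))
        scores = u[:, :a] * sv[:a]
        s2 = scores.var(axis=0, ddof=1)
        t2 = (scores**2 / s2[None, :]).sum(axis=1)
        t2_crit = _hotelling_crit(n, a, alpha)
        p = table.n_features
        resid = xc - scores @ vt[:a]
        dof = max(p - a, 1)
        s_i = np.sqrt((resid**2).sum(axis=1) / dof)
        denom = max((n - a - 1) * dof, 1)
        s0 = np.sqrt((resid**2).sum() / denom)
        dmodx = s_i / s0 if s0 > 0 else np.zeros(n)
        dmodx_crit = np.sqrt(stats.f.ppf(1 - alpha, dof, denom))
        for i, sid in enumerate(ids):
            rows.append(
                {
                    "sample_id": sid,
                    "group": group,
                    "t2": t2[i],
                    "t2_crit": t2_crit,
                    "t2_flag": bool(t2[i] > t2_crit),
                    "dmodx": dmodx[i],
                    "dmodx_crit": dmodx_crit,
                    "dmodx_flag": bool(dmodx[i] > dmodx_crit),
                    "n_components": a,
                }
            )
    return OutlierReport(table=pd.DataFrame(rows), alpha=alpha)


def preprocess(
    table: FeatureTable,
    filter_config: FilterConfig = FilterConfig(),
    rng: np.random.Generator | int | None = 0,
    pqn_reference: str = "auto",
    outlier_alpha: float | None = 0.05,
    drop_all_missing: bool = True,
) -> tuple[FeatureTable, PreprocessReport]:
    """The full pre-treatment chain in fixed order:
    filter -> impute -> PQN -> sqrt -> center -> Pareto (-> outlier screen).

    Returns the analysis-ready study matrix (centered/Pareto-scaled, so it may
    contain negatives) and a report bundling the filter flags, PQN quotients,
    degenerate features, and the optional PCA outlier screen.
    """
    qc_rows = table.subset_samples(table.role_mask(Role.QC))
    filtered, filter_report = filter_features(table, filter_config)
    qc_rows = qc_rows.subset_features(filter_report.retained_mask)
    imputed = impute_missing(filtered, rng=rng, drop_all_missing=drop_all_missing)
    if imputed.n_features != filtered.n_features:  # drop_all_missing removed some
        keep = np.isin(qc_rows.feature_names, imputed.feature_names)
        qc_rows = qc_rows.subset_features(keep)
    qc_complete = qc_rows if np.all(np.isfinite(qc_rows.intensities)) else None
    normalized, quotients = pqn_normalize(imputed, reference=pqn_reference, qc_table=qc_complete)
    scaled, degenerate = transform_scale(normalized)
    outliers = None
    if outlier_alpha is not None and scaled.case_mask.any() and scaled.control_mask.any():
        outliers = detect_outliers_pca(scaled, alpha=outlier_alpha)
    report = PreprocessReport(
        filter_report=filter_report,
        quotients=quotients,
        degenerate_features=degenerate,
        outlier_report=outliers,
    )
    return scaled, report
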