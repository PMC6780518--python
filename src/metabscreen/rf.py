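"""Balanced-subsample random-forest evaluation with held-out error curves.

When the two outcome groups are unequal, a forest trained on all samples
simply learns the majority class.  The procedure here instead draws many
balanced training subsets — each with floor(frac * min(group sizes)) samples
per class — trains one forest per subset, and scores it on every sample not
drawn.  The per-replicate held-out misclassification error (total and per
class, dubbed errOOB) is tracked as a function of the number of trees by
cumulative majority voting, and summarized by 10th/50th/90th percentiles
across replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "balanced_subsample_sizes",
    "rf_evaluate",
    "error_curve_summary",
    "RFEvaluationResult",
]

log = logging.getLogger(__name__)


def balanced_subsample_sizes(
    n_case: int, n_control: int, frac: float = 0.70
) -> tuple[int, int, int]:
    """Training-set sizes for one balanced draw: floor(frac * smaller group)
    per class, so (m, m, 2m)."""
    if n_case < 1 or n_control < 1:
        raise ValueError("both groups must be non-empty")
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    m = int(np.floor(frac * min(n_case, n_control)))
    if m < 1:
        raise ValueError(f"balanced subsample size is {m}; groups too small for frac={frac}")
    return m, m, 2 * m


@dataclass
class RFEvaluationResult:
    """Per-replicate held-out errors and error-vs-trees curves."""

    errors: pd.DataFrame  # rep, err_total, err_case, err_control, n_held, flagged
    curves_total: np.ndarray  # (n_reps, n_trees) error after k trees
    curves_case: np.ndarray
    curves_control: np.ndarray
    percentiles: dict[str, float]  # p10/p50/p90 of final total error
    m_case: int
    m_control: int

    @property
    def n_reps(self) -> int:
        return len(self.errors)

    @property
    def n_trees(self) -> int:
        return self.curves_total.shape[1]


def rf_evaluate(
    x: np.ndarray,
    is_case: np.ndarray,
    n_reps: int = 500,
    n_trees: int = 500,
    mtry: int = 40,
    frac: float = 0.70,
    rng: np.random.Generator | int | None = 0,
    bootstrap: bool = True,
) -> RFEvaluationResult:
    """Train ``n_reps`` forests on balanced subsets; score each on the rest.

    Candidate variables per split are min(mtry, p).  Voting ties at even tree
    counts go to the control class.  Deterministic given the rng seed.
    """
    x = np.asarray(x, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    if n_trees < 1 or n_reps < 1:
        raise ValueError("n_reps and n_trees must be >= 1")
    case_idx = np.flatnonzero(is_case)
    ctrl_idx = np.flatnonzero(~is_case)
    m, _, _ = balanced_subsample_sizes(len(case_idx), len(ctrl_idx), frac)
    if m == len(case_idx) and m == len(ctrl_idx):
        raise ValueError("frac leaves no held-out samples; nothing to evaluate")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    max_features = min(mtry, x.shape[1])

    rows = []
    curves_t = np.full((n_reps, n_trees), np.nan)
    curves_c = np.full((n_reps, n_trees), np.nan)
    curves_n = np.full((n_reps, n_trees), np.nan)
    for rep in range(n_reps):
        train = np.concatenate(
            [
                rng.choice(case_idx, size=m, replace=False),
                rng.choice(ctrl_idx, size=m, replace=False),
            ]
        )
        held = np.setdiff1d(np.arange(len(is_case)), train)
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=max_features,
            bootstrap=bootstrap,
            random_state=int(rng.integers(2**31 - 1)),
        )
        forest.fit(x[train], is_case[train].astype(int))
        # per-tree votes on the held-out set -> cumulative majority
        votes = np.stack([t.predict(x[held]) for t in forest.estimators_])  # (k, n_held)
        cum = np.cumsum(votes > 0.5, axis=0)
        k = np.arange(1, n_trees + 1)[:, None]
        pred = cum * 2 > k  # strict majority; tie -> control
        truth = is_case[held][None, :]
        wrong = pred != truth
        n_case_h = int(is_case[held].sum())
        n_ctrl_h = len(held) - n_case_h
        curves_t[rep] = wrong.mean(axis=1)
        flagged = False
        if n_case_h:
            curves_c[rep] = wrong[:, is_case[held]].mean(axis=1)
        else:
            flagged = True
        if n_ctrl_h:
            curves_n[rep] = wrong[:, ~is_case[held]].mean(axis=1)
        else:
            flagged = True
        if flagged:
            log.warning("rep %d: held-out set lacks a class; per-class error undefined", rep)
        rows.append(
            {
                "rep": rep,
                "err_total": curves_t[rep, -1],
                "err_case": curves_c[rep, -1],
                "err_control": curves_n[rep, -1],
                "n_held": len(held),
                "flagged": flagged,
            }
        )
    errors = pd.DataFrame(rows)
    final = errors["err_total"].to_numpy()
    pct = {f"p{k}": float(np.percentile(final, k)) for k in (10, 50, 90)}
    return RFEvaluationResult(
        errors=errors,
        curves_total=curves_t,
        curves_case=curves_c,
        curves_control=curves_n,
        percentiles=pct,
        m_case=m,
        m_control=m,
    )


def error_curve_summary(result: RFEvaluationResult, band_at: int | None = None) -> pd.DataFrame:
    """10/50/90 percentile curves of total and per-class error at every tree
    count, plus a min-max band of the total error at ``band_at`` trees
    (default: the final tree count)."""
    k = result.n_trees
    band_at = k if band_at is None else band_at
    if not 1 <= band_at <= k:
        raise ValueError(f"band_at must be in 1..{k}")
    out = {"n_trees": np.arange(1, k + 1)}
    for name, curves in (
        ("total", result.curves_total),
        ("case", result.curves_case),
        ("control", result.curves_control),
    ):
        for q in (10, 50, 90):
            out[f"{name}_p{q}"] = np.nanpercentile(curves, q, axis=0)
    df = pd.DataFrame(out)
    col = result.curves_total[:, band_at - 1]
    df.attrs["band"] = {
        "n_trees": band_at,
        "min": float(np.nanmin(col)),
        "max": float(np.nanmax(col)),
    }
    return df
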