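"""VIP-based PLS-DA with stability selection over balanced subsamples.

PLS-DA here is PLS1 regression (NIPALS, sequential deflation) against a
centered +1/-1 class response.  Feature importance is the variable influence
on projection (VIP), normalized so that the mean squared VIP equals 1; the
VIP cut-off is not fixed a priori but chosen, together with the component
count, by maximizing 7-fold cross-validated R^2 (Q^2) of the model refit on
the surviving features.

The stability wrapper repeats this selection on many random subsamples, each
containing 75% of the cases and an equal number of controls; features kept in
more than half of the models form the stable set.  Each model's predictive
value is summarized by the AUC of its continuous predictions on the samples
it never saw (AUCpred), and class membership on those samples is assigned by
linear discriminant analysis on the model's score space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .univariate import roc_auc

__all__ = [
    "PLSModel",
    "fit_pls",
    "vip_scores",
    "VIPSelection",
    "select_vip_threshold",
    "lda_classify_scores",
    "StabilitySelectionResult",
    "stability_selection",
    "DEFAULT_VIP_GRID",
]

log = logging.getLogger(__name__)

DEFAULT_VIP_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.6, 1.61, 0.1), 1))

_TOL = 1e-12


@dataclass
class PLSModel:
    """A fitted PLS1 model (rows = samples, columns = features).

    Weight columns have unit norm; the sign indeterminacy of each component
    is resolved by forcing its largest-magnitude weight entry positive.
    """

    weights: np.ndarray  # (p, A), unit-norm columns
    scores: np.ndarray  # (n, A)
    loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (A,)
    x_mean: np.ndarray  # (p,)
    y_mean: float
    y_train: np.ndarray  # original encoded response, for LDA on scores

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]

    def rotation(self, a: int | None = None) -> np.ndarray:
        """R = W (P'W)^-1 such that T = (X - mean) R."""
        a = self.n_components if a is None else a
        w, pl = self.weights[:, :a], self.loadings[:, :a]
        return w @ np.linalg.inv(pl.T @ w)

    def coef(self, a: int | None = None) -> np.ndarray:
        a = self.n_components if a is None else a
        return self.rotation(a) @ self.y_loadings[:a]

    def transform(self, x_new: np.ndarray, a: int | None = None) -> np.ndarray:
        return (np.asarray(x_new, dtype=float) - self.x_mean) @ self.rotation(a)

    def predict(self, x_new: np.ndarray, a: int | None = None) -> np.ndarray:
        return self.y_mean + (np.asarray(x_new, dtype=float) - self.x_mean) @ self.coef(a)


def fit_pls(x: np.ndarray, y: np.ndarray, a: int, strict: bool = True) -> PLSModel:
    """Fit PLS1 by NIPALS with sequential deflation.

    ``x`` is samples x features; ``y`` is the numeric class response (+1/-1
    for PLS-DA).  Centering is internal.  With ``strict`` the requested number
    of components must be reachable (a deflated cross-covariance of zero means
    ``a`` exceeds the predictive rank); otherwise extraction stops early.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if len(y) != n:
        raise ValueError("x and y have incompatible shapes")
    if a < 1:
        raise ValueError("need at least one component")
    x_mean = x.mean(axis=0)
    y_mean = float(y.mean())
    xr = x - x_mean
    if not np.any(xr):
        raise ValueError("zero-variance X: nothing to fit")
    yr = y - y_mean
    scale = max(float(np.abs(xr).max() * np.abs(yr).max()), 1.0)
    ws, ts, ps, qs = [], [], [], []
    for _ in range(a):
        w = xr.T @ yr
        nw = float(np.linalg.norm(w))
        if nw <= _TOL * scale:
            if strict:
                raise ValueError(
                    f"requested {a} components but predictive rank is {len(ws)}"
                )
            break
        w = w / nw
        jmax = int(np.argmax(np.abs(w)))
        if w[jmax] < 0:
            w = -w
        t = xr @ w
        tt = float(t @ t)
        if tt <= _TOL * scale:
            if strict:
                raise ValueError(f"degenerate score on component {len(ws) + 1}")
            break
        q = float(t @ yr) / tt
        pl = xr.T @ t / tt
        xr = xr - np.outer(t, pl)
        yr = yr - q * t
        ws.append(w)
        ts.append(t)
        ps.append(pl)
        qs.append(q)
    if not ws:
        raise ValueError("no component could be extracted (y orthogonal to X)")
    return PLSModel(
        weights=np.column_stack(ws),
        scores=np.column_stack(ts),
        loadings=np.column_stack(ps),
        y_loadings=np.array(qs),
        x_mean=x_mean,
        y_mean=y_mean,
        y_train=y,
    )


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable influence on projection:
    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ),
    with SSY_a = q_a^2 (t_a' t_a) and unit-norm weights; sum_j VIP_j^2 = p."""
    ssy = model.y_loadings**2 * np.einsum("ia,ia->a", model.scores, model.scores)
    total = ssy.sum()
    if total <= 0:
        raise ValueError("degenerate model: all components explain zero Y variance")
    return np.sqrt(model.n_features * (model.weights**2 @ ssy) / total)


def _stratified_folds(y: np.ndarray, n_folds: int) -> list[np.ndarray]:
    """Deterministic stratified folds: indices of each class dealt round-robin."""
    y = np.asarray(y)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        for k, i in enumerate(idx):
            folds[(k + offset) % n_folds].append(int(i))
        offset += len(idx)  # stagger classes across folds
    return [np.array(sorted(f), dtype=int) for f in folds if len(f)]


def _cv_q2(x: np.ndarray, y: np.ndarray, a_max: int, n_folds: int) -> np.ndarray:
    """Q^2 = 1 - PRESS/TSS for each component count 1..a_max by stratified CV."""
    n = len(y)
    folds = _stratified_folds(y > np.mean(y), n_folds)
    press = np.zeros(a_max)
    for test_idx in folds:
        train = np.setdiff1d(np.arange(n), test_idx)
        model = fit_pls(x[train], y[train], a_max, strict=False)
        for a in range(1, a_max + 1):
            aa = min(a, model.n_components)
            pred = model.predict(x[test_idx], a=aa)
            press[a - 1] += float(((y[test_idx] - pred) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / tss


@dataclass
class VIPSelection:
    """Outcome of the CV-optimized VIP threshold search."""

    threshold: float
    n_components: int
    cv_r2: float
    support: np.ndarray  # (p,) bool: features surviving the chosen threshold
    vip: np.ndarray  # (p,) VIP from the full-feature model
    model: PLSModel  # refit on the surviving features


def select_vip_threshold(
    x: np.ndarray,
    y: np.ndarray,
    threshold_grid: tuple[float, ...] = DEFAULT_VIP_GRID,
    a_max: int = 5,
    n_folds: int = 7,
) -> VIPSelection:
    """Choose the VIP cut-off (and component count) maximizing cross-validated R^2.

    For each candidate threshold the full model's VIPs define the surviving
    feature set; the model refit on that set is scored by ``n_folds``-fold Q^2
    over component counts 1..a_max.  Ties break toward the larger threshold
    (the sparser model).  Negative Q^2 is allowed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if n < 2 * n_folds:
        raise ValueError(f"need >= {2 * n_folds} samples for {n_folds}-fold CV")
    a_cap = max(1, min(a_max, n - int(np.ceil(n / n_folds)) - 1, p))
    q2_full = _cv_q2(x, y, a_cap, n_folds)
    a_full = int(np.argmax(q2_full)) + 1
    full_model = fit_pls(x, y, a_full, strict=False)
    vip = vip_scores(full_model)

    best: tuple[float, float, int, np.ndarray] | None = None  # q2, thr, a, mask
    for thr in sorted(threshold_grid):
        mask = vip >= thr
        if not mask.any():
            continue
        a_k = max(1, min(a_cap, int(mask.sum())))
        q2 = _cv_q2(x[:, mask], y, a_k, n_folds)
        a_best = int(np.argmax(q2)) + 1
        if best is None or q2[a_best - 1] >= best[0]:
            best = (float(q2[a_best - 1]), float(thr), a_best, mask)
    if best is None:
        raise ValueError("every candidate threshold removed all features")
    q2_best, thr_best, a_best, mask_best = best
    refit = fit_pls(x[:, mask_best], y, a_best, strict=False)
    support = np.zeros(p, dtype=bool)
    support[np.flatnonzero(mask_best)] = True
    return VIPSelection(
        threshold=thr_best,
        n_components=refit.n_components,
        cv_r2=q2_best,
        support=support,
        vip=vip,
        model=refit,
    )


def lda_classify_scores(model: PLSModel, x_new: np.ndarray) -> np.ndarray:
    """Class membership of new samples by LDA on the PLS score space.

    Pooled-covariance linear discriminant with empirical priors, fit on the
    training scores; a singular pooled covariance falls back to a ridge
    (1e-6 on the diagonal).  Returns a boolean is-case array; exact ties on
    the decision boundary go to the control class.
    """
    t_train = model.scores
    is_case = model.y_train > model.y_train.mean()
    if is_case.all() or not is_case.any():
        raise ValueError("LDA needs both classes in the training response")
    t_new = model.transform(x_new)
    m1 = t_train[is_case].mean(axis=0)
    m0 = t_train[~is_case].mean(axis=0)
    d1 = t_train[is_case] - m1
    d0 = t_train[~is_case] - m0
    n = len(t_train)
    s = (d1.T @ d1 + d0.T @ d0) / max(n - 2, 1)
    try:
        s_inv = np.linalg.inv(s)
        if not np.all(np.isfinite(s_inv)) or np.linalg.cond(s) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        log.info("singular pooled covariance in LDA; applying ridge 1e-6")
        s_inv = np.linalg.inv(s + 1e-6 * np.eye(s.shape[0]))
    pi1 = is_case.mean()
    pi0 = 1.0 - pi1
    def disc(m: np.ndarray, prior: float) -> np.ndarray:
        return t_new @ s_inv @ m - 0.5 * m @ s_inv @ m + np.log(prior)
    return disc(m1, pi1) > disc(m0, pi0)  # tie -> control


@dataclass
class StabilitySelectionResult:
    """Aggregated outcome of the subsample-and-select procedure."""

    counts: pd.Series  # per-feature selection count N over the n_models
    selected: pd.Series  # bool, N > freq_threshold * n_models (or >= if inclusive)
    n_models: int
    auc_pred: np.ndarray  # per-model held-out AUC (NaN if one class absent)
    auc_percentiles: dict[str, float]  # keys p10, p50, p90
    confusion: pd.DataFrame  # per-model tn, fp, fn, tp on held-out samples
    roc_curves: list[tuple[np.ndarray, np.ndarray]]  # (fpr, tpr) per model
    train_indices: list[np.ndarray]  # bookkeeping: who trained each model
    thresholds: np.ndarray  # chosen VIP threshold per model
    components: np.ndarray  # chosen component count per model

    @property
    def selected_names(self) -> list[str]:
        return list(self.selected.index[self.selected])


def stability_selection(
    x: np.ndarray,
    is_case: np.ndarray,
    n_sub: int = 100,
    case_frac: float = 0.75,
    freq_threshold: float = 0.5,
    rng: np.random.Generator | int | None = 0,
    threshold_grid: tuple[float, ...] = DEFAULT_VIP_GRID,
    a_max: int = 5,
    n_folds: int = 7,
    freq_inclusive: bool = False,
    feature_names: list[str] | None = None,
) -> StabilitySelectionResult:
    """Run VIP-based PLS-DA selection over ``n_sub`` balanced subsamples.

    Each subsample draws floor(case_frac * n_case) cases and the same number
    of controls without replacement; the VIP threshold search runs on the
    subsample alone, and the refit model is evaluated (continuous predictions
    -> AUCpred; LDA on scores -> confusion matrix) on every sample NOT drawn.
    """
    from sklearn.metrics import roc_curve

    x = np.asarray(x, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    if n_sub < 1:
        raise ValueError("n_sub must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    case_idx = np.flatnonzero(is_case)
    ctrl_idx = np.flatnonzero(~is_case)
    if len(case_idx) < 4 or len(ctrl_idx) < 4:
        raise ValueError("stability selection needs >= 4 samples per class")
    m = int(np.floor(case_frac * len(case_idx)))
    if m < 2:
        raise ValueError(f"subsample size per class is {m}; need >= 2")
    if m > len(ctrl_idx):
        raise ValueError("not enough controls for a balanced subsample")

    p = x.shape[1]
    names = feature_names if feature_names is not None else [f"f{j}" for j in range(p)]
    y = np.where(is_case, 1.0, -1.0)
    counts = np.zeros(p, dtype=int)
    aucs = np.full(n_sub, np.nan)
    conf_rows = []
    curves: list[tuple[np.ndarray, np.ndarray]] = []
    train_list: list[np.ndarray] = []
    thr_arr = np.zeros(n_sub)
    comp_arr = np.zeros(n_sub, dtype=int)
    for b in range(n_sub):
        train = np.sort(
            np.concatenate(
                [
                    rng.choice(case_idx, size=m, replace=False),
                    rng.choice(ctrl_idx, size=m, replace=False),
                ]
            )
        )
        held = np.setdiff1d(np.arange(len(y)), train)
        sel = select_vip_threshold(
            x[train], y[train], threshold_grid=threshold_grid, a_max=a_max, n_folds=n_folds
        )
        counts += sel.support
        thr_arr[b] = sel.threshold
        comp_arr[b] = sel.n_components
        train_list.append(train)
        if len(held) and is_case[held].any() and (~is_case[held]).any():
            pred = sel.model.predict(x[held][:, sel.support])
            auc, _, _ = roc_auc(pred, is_case[held])
            aucs[b] = auc
            fpr, tpr, _ = roc_curve(is_case[held], pred)
            curves.append((fpr, tpr))
            pred_case = lda_classify_scores(sel.model, x[held][:, sel.support])
            tp = int((pred_case & is_case[held]).sum())
            tn = int((~pred_case & ~is_case[held]).sum())
            fp = int((pred_case & ~is_case[held]).sum())
            fn = int((~pred_case & is_case[held]).sum())
            conf_rows.append({"model": b, "tn": tn, "fp": fp, "fn": fn, "tp": tp})
        else:
            log.warning("model %d: held-out set lacks a class; AUCpred undefined", b)
    cut = freq_threshold * n_sub
    sel_mask = counts >= cut if freq_inclusive else counts > cut
    pct = {
        f"p{k}": float(np.nanpercentile(aucs, k)) if np.isfinite(aucs).any() else float("nan")
        for k in (10, 50, 90)
    }
    return StabilitySelectionResult(
        counts=pd.Series(counts, index=names, name="n_selected"),
        selected=pd.Series(sel_mask, index=names, name="selected"),
        n_models=n_sub,
        auc_pred=aucs,
        auc_percentiles=pct,
        confusion=pd.DataFrame(conf_rows, columns=["model", "tn", "fp", "fn", "tp"]),
        roc_curves=curves,
        train_indices=train_list,
        thresholds=thr_arr,
        components=comp_arr,
    )
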