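"""Synthetic untargeted LC-MS feature tables with known ground truth.

The generator emulates the statistical structure a urine-metabolomics
discrimination analysis assumes, so every downstream stage can be exercised
with known answers:

* log-normal feature intensities with per-feature baseline ``mu_j`` and a
  shared log-scale SD ``sigma``;
* a multiplicative per-sample dilution factor ``d_i = exp(N(0, tau^2))`` —
  the structure probabilistic quotient normalization corrects;
* a planted subset of case-associated features shifted by ``+/- delta`` on
  the log scale (direction random per feature);
* left-censored missingness: intensities below each feature's
  ``missing_rate`` quantile are dropped, mimicking below-detection peaks;
* pooled-QC replicates with a calibrated low coefficient of variation and no
  censoring, and near-empty solvent blanks with occasional background peaks
  two orders of magnitude below the study median.

Features are labelled with retention times uniform in [0.5, 7.0] min and
masses uniform in the 20-1200 amu acquisition window.  Independence across
features is assumed (no adduct/isotope correlation, no drift or batches).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .feature_table import (
    FeatureID,
    FeatureTable,
    Label,
    MassKind,
    Role,
    SampleRecord,
    format_feature_id,
)

__all__ = ["SyntheticConfig", "GroundTruth", "generate_dataset", "planted_effect_check"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shaped defaults: a high-risk birth cohort of 171 neonates with a
    ~12% case fraction measured on 1555 features, ~20 of them truly
    case-associated at about 1.5 log-units."""

    n_cases: int = 20
    n_controls: int = 151
    n_qc: int = 10
    n_blank: int = 5
    n_features: int = 1555
    n_discriminative: int = 20
    effect_size: float = 1.5  # delta, log-intensity shift on planted features
    dilution_sd: float = 0.3  # tau, SD of log dilution factor
    base_log_mean_range: tuple[float, float] = (6.0, 12.0)  # mu_j ~ U(range)
    base_log_sd: float = 1.0  # sigma, within-group log-scale SD
    qc_cv: float = 0.10  # target CV of pooled-QC replicates
    missing_rate: float = 0.20  # left-censoring quantile
    blank_detect_rate: float = 0.02  # P(feature appears in a blank injection)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_cases=self.n_cases,
            n_controls=self.n_controls,
            n_qc=self.n_qc,
            n_blank=self.n_blank,
            n_features=self.n_features,
            n_discriminative=self.n_discriminative,
        )
        for k, v in counts.items():
            if v < 0:
                raise ValueError(f"{k} must be >= 0, got {v}")
        if self.n_discriminative > self.n_features:
            raise ValueError("n_discriminative cannot exceed n_features")
        for k in ("missing_rate", "blank_detect_rate"):
            v = getattr(self, k)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{k} must be in [0, 1], got {v}")
        if self.dilution_sd < 0 or self.base_log_sd <= 0 or self.qc_cv < 0:
            raise ValueError("dilution_sd, base_log_sd, qc_cv must be nonnegative (sd > 0)")
        lo, hi = self.base_log_mean_range
        if not lo <= hi:
            raise ValueError("base_log_mean_range must be (lo, hi) with lo <= hi")


@dataclass
class GroundTruth:
    """What was planted: which features discriminate, in which direction, and
    each study sample's true dilution factor."""

    discriminative: list[FeatureID]
    directions: dict[str, int]  # formatted id -> +1 (case-up) / -1 (case-down)
    dilution: dict[str, float]  # study sample id -> d_i

    @property
    def discriminative_names(self) -> set[str]:
        return {format_feature_id(f) for f in self.discriminative}


def _draw_feature_ids(n: int, rng: np.random.Generator) -> list[FeatureID]:
    ids: list[FeatureID] = []
    seen: set[str] = set()
    while len(ids) < n:
        rt = rng.uniform(0.5, 7.0)
        mass = rng.uniform(20.0, 1200.0)
        kind = MassKind.MZ if rng.random() < 0.8 else MassKind.NEUTRAL
        fid = FeatureID(rt=rt, mass=mass, mass_kind=kind)
        name = format_feature_id(fid)
        if name not in seen:  # retry on the (rare) display-precision collision
            seen.add(name)
            ids.append(fid)
    return ids


def generate_dataset(config: SyntheticConfig) -> tuple[FeatureTable, GroundTruth]:
    """Generate one feature table (study + QC + blank rows) and its ground truth.

    Deterministic given ``config.seed``: two calls with the same config return
    bitwise-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_features
    n_study = config.n_cases + config.n_controls

    features = _draw_feature_ids(p, rng)
    mu = rng.uniform(*config.base_log_mean_range, size=p)
    planted_idx = rng.choice(p, size=config.n_discriminative, replace=False)
    direction = np.zeros(p)
    direction[planted_idx] = rng.choice([-1.0, 1.0], size=config.n_discriminative)
    delta = np.zeros(p)
    delta[planted_idx] = config.effect_size

    is_case = np.zeros(n_study, dtype=bool)
    is_case[: config.n_cases] = True
    d = np.exp(rng.normal(0.0, config.dilution_sd, size=n_study))

    # latent log-intensities z_ij = mu_j + delta_j * s_j * 1[case] + N(0, sigma^2)
    z = (
        mu[None, :]
        + np.outer(is_case.astype(float), delta * direction)
        + rng.normal(0.0, config.base_log_sd, size=(n_study, p))
    )
    x_study = d[:, None] * np.exp(z)

    # left-censor below the per-feature missing_rate quantile of study samples
    if config.missing_rate > 0 and n_study > 0:
        thresh = np.quantile(x_study, config.missing_rate, axis=0)
        x_study = np.where(x_study < thresh[None, :], np.nan, x_study)

    # QC replicates: pooled mean spectrum with multiplicative noise at qc_cv
    if config.n_qc > 0:
        qc_base = np.exp(z.mean(axis=0)) if n_study > 0 else np.exp(mu)
        s_qc = np.sqrt(np.log1p(config.qc_cv**2))  # lognormal sigma with CV = qc_cv
        x_qc = qc_base[None, :] * np.exp(rng.normal(0.0, s_qc, size=(config.n_qc, p)))
    else:
        x_qc = np.empty((0, p))

    # blanks: mostly missing, occasional background two decades below study median
    if config.n_blank > 0:
        detected = rng.random(size=(config.n_blank, p)) < config.blank_detect_rate
        study_med = np.nanmedian(x_study, axis=0) if n_study > 0 else np.exp(mu)
        study_med = np.where(np.isfinite(study_med), study_med, np.exp(mu))
        bg = (study_med[None, :] / 100.0) * np.exp(
            rng.normal(0.0, 0.3, size=(config.n_blank, p))
        )
        x_blank = np.where(detected, bg, np.nan)
    else:
        x_blank = np.empty((0, p))

    samples: list[SampleRecord] = []
    for i in range(n_study):
        samples.append(
            SampleRecord(
                sample_id=f"S{i + 1:04d}",
                role=Role.STUDY,
                label=Label.CASE if is_case[i] else Label.CONTROL,
            )
        )
    samples += [SampleRecord(sample_id=f"QC{i + 1:03d}", role=Role.QC) for i in range(config.n_qc)]
    samples += [
        SampleRecord(sample_id=f"BL{i + 1:03d}", role=Role.BLANK) for i in range(config.n_blank)
    ]

    table = FeatureTable(
        samples=samples,
        features=features,
        intensities=np.vstack([x_study, x_qc, x_blank]),
    )
    truth = GroundTruth(
        discriminative=[features[j] for j in sorted(planted_idx)],
        directions={
            format_feature_id(features[j]): int(direction[j]) for j in sorted(planted_idx)
        },
        dilution={samples[i].sample_id: float(d[i]) for i in range(n_study)},
    )
    return table, truth


def planted_effect_check(table: FeatureTable, truth: GroundTruth) -> pd.DataFrame:
    """Empirical standardized case-vs-control shift for each planted feature.

    Works on the log scale after dividing out the known dilution factors; the
    shift is oriented by the planted direction and standardized by the pooled
    SD, so with ``base_log_sd = 1`` its expectation is ``effect_size``.
    """
    dil = np.array([truth.dilution.get(s.sample_id, np.nan) for s in table.samples])
    study = table.study_mask
    if np.any(study & ~np.isfinite(dil)):
        raise ValueError("table/truth mismatch: study sample missing from ground-truth dilution")
    case = table.case_mask
    ctrl = table.control_mask
    rows = []
    names = table.feature_names
    for name in sorted(truth.directions):
        if name not in names:
            raise ValueError(f"table/truth mismatch: planted feature {name} not in table")
        j = names.index(name)
        logx = np.log(table.intensities[:, j] / dil)
        vc = logx[case & np.isfinite(logx)]
        vn = logx[ctrl & np.isfinite(logx)]
        if len(vc) > 1 and len(vn) > 1:
            pooled = np.sqrt(
                ((len(vc) - 1) * vc.var(ddof=1) + (len(vn) - 1) * vn.var(ddof=1))
                / (len(vc) + len(vn) - 2)
            )
            shift = truth.directions[name] * (vc.mean() - vn.mean()) / pooled
        else:
            shift = np.nan
        rows.append(
            {
                "feature": name,
                "direction": truth.directions[name],
                "standardized_shift": shift,
                "n_case_present": len(vc),
                "n_control_present": len(vn),
            }
        )
    return pd.DataFrame(rows, columns=["feature", "direction", "standardized_shift", "n_case_present", "n_control_present"])
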