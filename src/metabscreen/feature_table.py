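"""Domain types and I/O for processed LC-MS feature tables.

Untargeted LC-MS peak-picking software exports wide intensity matrices whose
columns are named ``<Rt>_<mass><kind>``, where ``Rt`` is the chromatographic
retention time in minutes and the mass is either an adduct ion mass ("m/z")
or a deconvolved neutral mass ("n") summed over adducts.  This module models
those identifiers, the per-sample metadata (study / QC / blank / mix roles and
binary outcome labels), and a simple delimited-text round-trip: a purely
numeric intensity matrix plus a sample-sheet sidecar.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MassKind",
    "Role",
    "Label",
    "FeatureID",
    "SampleRecord",
    "FeatureTable",
    "DialectConfig",
    "parse_feature_id",
    "format_feature_id",
    "read_feature_table",
    "write_feature_table",
    "FeatureTableError",
]


class FeatureTableError(ValueError):
    """Raised on malformed identifiers or invalid tables."""


class MassKind(str, enum.Enum):
    MZ = "m/z"
    NEUTRAL = "n"


class Role(str, enum.Enum):
    STUDY = "study"
    QC = "qc"
    BLANK = "blank"
    MIX = "mix"


class Label(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"


@dataclass(frozen=True, order=True)
class FeatureID:
    """An LC-MS feature: retention time (min) + mass (amu) + mass kind.

    Values are stored at display precision (rt: 2 decimals, mass: 4 decimals)
    so that ``parse_feature_id(format_feature_id(f)) == f`` holds exactly.
    """

    rt: float
    mass: float
    mass_kind: MassKind = MassKind.MZ

    def __post_init__(self) -> None:
        object.__setattr__(self, "rt", round(float(self.rt), 2))
        object.__setattr__(self, "mass", round(float(self.mass), 4))
        if self.rt < 0:
            raise FeatureTableError(f"retention time must be >= 0, got {self.rt}")
        if self.mass <= 0:
            raise FeatureTableError(f"mass must be > 0, got {self.mass}")

    def __str__(self) -> str:
        return format_feature_id(self)


_ID_RE = re.compile(
    r"^\s*(?P<rt>[0-9]+(?:\.[0-9]+)?)\s*_\s*(?P<mass>[0-9]+(?:\.[0-9]+)?)\s*(?P<kind>m/z|n)\s*$"
)


def parse_feature_id(text: str) -> FeatureID:
    """Parse ``"2.38_425.0667m/z"`` or ``"4.95_520.1083n"`` into a FeatureID."""
    m = _ID_RE.match(text)
    if m is None:
        # diagnose which token is bad for a helpful message
        parts = re.split(r"_", text.strip(), maxsplit=1)
        if len(parts) != 2:
            raise FeatureTableError(f"malformed feature id {text!r}: expected '<rt>_<mass><kind>'")
        rt_tok, rest = parts
        try:
            float(rt_tok)
        except ValueError:
            raise FeatureTableError(f"malformed feature id {text!r}: bad retention time token {rt_tok!r}") from None
        kind_m = re.search(r"(m/z|n)\s*$", rest)
        if kind_m is None:
            raise FeatureTableError(f"malformed feature id {text!r}: unknown mass kind in {rest!r}")
        raise FeatureTableError(f"malformed feature id {text!r}: bad mass token {rest[: kind_m.start()]!r}")
    return FeatureID(
        rt=float(m.group("rt")),
        mass=float(m.group("mass")),
        mass_kind=MassKind(m.group("kind")),
    )


def format_feature_id(fid: FeatureID) -> str:
    """Format with rt to 2 decimals and mass to 4 decimals, e.g. ``2.38_425.0667m/z``."""
    return f"{fid.rt:.2f}_{fid.mass:.4f}{fid.mass_kind.value}"


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    role: Role
    label: Label | None = None
    cohort: str | None = None

    def __post_init__(self) -> None:
        if self.role is not Role.STUDY and self.label is not None:
            raise FeatureTableError(
                f"sample {self.sample_id!r}: outcome labels are only valid for study samples"
            )


@dataclass
class FeatureTable:
    """Intensity matrix over samples x features with roles and outcome labels.

    ``intensities`` is float with NaN marking missing values; all present
    values must be nonnegative (pre-transformation scale).  Set
    ``allow_negative=True`` after centering/scaling stages.
    """

    samples: list[SampleRecord]
    features: list[FeatureID]
    intensities: np.ndarray
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        n, p = len(self.samples), len(self.features)
        if self.intensities.shape != (n, p):
            raise FeatureTableError(
                f"intensity matrix shape {self.intensities.shape} != ({n}, {p})"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FeatureTableError(f"duplicate sample ids: {dup}")
        names = [format_feature_id(f) for f in self.features]
        if len(set(names)) != len(names):
            dup = sorted({i for i in names if names.count(i) > 1})
            raise FeatureTableError(f"duplicate feature ids: {dup}")
        if not self.allow_negative and np.nanmin(self.intensities, initial=0.0) < 0:
            raise FeatureTableError("negative intensities are not allowed before transformation")

    # -- convenience views -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return [format_feature_id(f) for f in self.features]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def role_mask(self, role: Role) -> np.ndarray:
        return np.array([s.role is role for s in self.samples], dtype=bool)

    @property
    def study_mask(self) -> np.ndarray:
        return self.role_mask(Role.STUDY)

    @property
    def case_mask(self) -> np.ndarray:
        """True for study samples labelled case (False elsewhere)."""
        return np.array(
            [s.role is Role.STUDY and s.label is Label.CASE for s in self.samples], dtype=bool
        )

    @property
    def control_mask(self) -> np.ndarray:
        return np.array(
            [s.role is Role.STUDY and s.label is Label.CONTROL for s in self.samples], dtype=bool
        )

    def subset_samples(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        return FeatureTable(
            samples=[s for s, m in zip(self.samples, mask) if m],
            features=list(self.features),
            intensities=self.intensities[mask],
            allow_negative=self.allow_negative,
        )

    def subset_features(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        return FeatureTable(
            samples=list(self.samples),
            features=[f for f, m in zip(self.features, mask) if m],
            intensities=self.intensities[:, mask],
            allow_negative=self.allow_negative,
        )

    def with_intensities(self, x: np.ndarray, allow_negative: bool | None = None) -> "FeatureTable":
        return FeatureTable(
            samples=list(self.samples),
            features=list(self.features),
            intensities=x,
            allow_negative=self.allow_negative if allow_negative is None else allow_negative,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, index=self.sample_ids, columns=self.feature_names)

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.samples == other.samples
            and self.features == other.features
            and np.array_equal(self.intensities, other.intensities, equal_nan=True)
        )


@dataclass(frozen=True)
class DialectConfig:
    """Text-dialect options for matrix/sample-sheet I/O.

    ``zero_is_missing`` maps literal 0 to missing on read: peak-table exports
    frequently write 0 for undetected peaks, and downstream imputation assumes
    below-detection missingness.
    """

    delimiter: str = "\t"
    zero_is_missing: bool = True
    decimal: str = "."


def _samples_path(path: Path) -> Path:
    return path.with_name(path.stem + ".samples.tsv")


def read_feature_table(
    path: str | Path,
    samples_path: str | Path | None = None,
    dialect: DialectConfig = DialectConfig(),
) -> FeatureTable:
    """Read an intensity matrix plus its sample-sheet sidecar.

    The matrix file has one header row of formatted feature ids and one row
    per sample (first column = sample id).  The sidecar is a TSV with columns
    sample_id, role, label, cohort.  Empty cells are missing; literal zeros
    are mapped to missing when ``dialect.zero_is_missing``.
    """
    path = Path(path)
    sp = Path(samples_path) if samples_path is not None else _samples_path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(dialect.delimiter)[1:]
    if len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise FeatureTableError(f"duplicate feature ids in header: {dup}")
    df = pd.read_csv(
        path,
        sep=dialect.delimiter,
        index_col=0,
        decimal=dialect.decimal,
        float_precision="round_trip",
    )
    meta = pd.read_csv(sp, sep="\t", dtype=str, keep_default_na=False)
    if "role" not in meta.columns or "sample_id" not in meta.columns:
        raise FeatureTableError(f"sample sheet {sp} must have sample_id and role columns")
    features = [parse_feature_id(c) for c in df.columns]
    meta = meta.set_index("sample_id")
    samples = []
    for sid in df.index.astype(str):
        if sid not in meta.index:
            raise FeatureTableError(f"sample {sid!r} missing from sample sheet")
        row = meta.loc[sid]
        label = row.get("label", "")
        cohort = row.get("cohort", "")
        samples.append(
            SampleRecord(
                sample_id=sid,
                role=Role(row["role"]),
                label=Label(label) if label else None,
                cohort=cohort or None,
            )
        )
    x = df.to_numpy(dtype=float)
    if np.nanmin(x, initial=0.0) < 0:
        raise FeatureTableError(f"negative intensities in {path}")
    if dialect.zero_is_missing:
        x = np.where(x == 0.0, np.nan, x)
    return FeatureTable(samples=samples, features=features, intensities=x)


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    samples_path: str | Path | None = None,
    dialect: DialectConfig = DialectConfig(),
) -> None:
    """Write the matrix (missing as empty cells) and the sample sheet."""
    path = Path(path)
    sp = Path(samples_path) if samples_path is not None else _samples_path(path)
    table.to_dataframe().to_csv(
        path,
        sep=dialect.delimiter,
        na_rep="",
        decimal=dialect.decimal,
        index_label="sample_id",
        float_format="%.17g",  # lossless round-trip
    )
    rows = [
        {
            "sample_id": s.sample_id,
            "role": s.role.value,
            "label": s.label.value if s.label else "",
            "cohort": s.cohort or "",
        }
        for s in table.samples
    ]
    pd.DataFrame(rows, columns=["sample_id", "role", "label", "cohort"]).to_csv(
        sp, sep="\t", index=False
    )
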