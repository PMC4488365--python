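"""Long-format repeated-measures containers and baseline-covariate handling.

The analysis operates on two tables:

* a *trajectory panel*: one row per (subject, visit) with the visit age in
  years and the outcome value (BMI in kg/m^2 for the motivating application);
* a *baseline table*: one row per subject with sex, exposure concentrations
  (lipid-adjusted, ng/g lipid, analysed on the log10 scale) and confounders.

Missing visits are simply absent rows; subjects enter a model fit only if
they have enough observed visits (default: at least 4 of the 5 nominal
visits at ages 2, 3.5, 5, 7 and 9 years).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelError",
    "ConfigError",
    "TrajectoryPanel",
    "BaselineTable",
    "ExposureSpec",
    "read_long_panel",
    "read_baseline_table",
    "compute_bmi",
    "preprocess_exposure",
    "preprocess_exposure_series",
    "filter_min_visits",
    "stratify",
]

#: recognised sensitivity-subset rules for :func:`stratify`
SUBSET_RULES = ("exclude_preterm", "exclude_low_birth_weight")


class PanelError(ValueError):
    """Invalid panel content (duplicates, bad ages, empty input...)."""


class ConfigError(ValueError):
    """Configuration problem: missing columns, unresolvable names."""


@dataclass(frozen=True)
class ExposureSpec:
    """An exposure analysed on the log10 scale, with a limit of detection.

    Concentrations below the LOD are imputed at LOD/2 before the log10
    transform, the standard substitution for left-censored assay values.
    """

    name: str
    lod: float | None = None

    def __post_init__(self) -> None:
        if self.lod is not None and not self.lod > 0:
            raise ValueError(f"LOD for {self.name!r} must be > 0, got {self.lod}")


class TrajectoryPanel:
    """Immutable long-format panel of repeated measures.

    Rows are kept in deterministic subject-then-age order.  Each
    (subject, age) pair occurs at most once, ages are finite and strictly
    positive, and every subject has at least one record.
    """

    def __init__(self, records: pd.DataFrame):
        df = records.loc[:, ["subject_id", "age", "value"]].copy()
        if len(df) == 0:
            raise PanelError("no records")
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        if df["age"].isna().any():
            bad = int(df.index[df["age"].isna()][0])
            raise PanelError(f"non-numeric or missing age at row {bad}")
        if df["value"].isna().any():
            bad = int(df.index[df["value"].isna()][0])
            raise PanelError(f"non-numeric or missing value at row {bad}")
        if not np.isfinite(df["age"]).all() or (df["age"] <= 0).any():
            raise PanelError("ages must be finite and strictly positive")
        if not np.isfinite(df["value"]).all():
            raise PanelError("values must be finite")
        dup = df.duplicated(subset=["subject_id", "age"])
        if dup.any():
            sid, age = df.loc[dup.idxmax(), ["subject_id", "age"]]
            raise PanelError(f"duplicate record for subject {sid!r} at age {age}")
        df = df.sort_values(["subject_id", "age"], kind="mergesort").reset_index(drop=True)
        self._df = df

    @property
    def records(self) -> pd.DataFrame:
        """Long-format records, subject-then-age ordered (copy)."""
        return self._df.copy()

    @property
    def subjects(self) -> list:
        return list(self._df["subject_id"].unique())

    @property
    def n_subjects(self) -> int:
        return self._df["subject_id"].nunique()

    def __len__(self) -> int:
        return len(self._df)

    def visit_counts(self) -> pd.Series:
        return self._df.groupby("subject_id", sort=True).size()

    def iter_subjects(self) -> Iterator[tuple[object, np.ndarray, np.ndarray]]:
        """Yield (subject_id, ages, values) in deterministic order."""
        for sid, grp in self._df.groupby("subject_id", sort=True):
            yield sid, grp["age"].to_numpy(), grp["value"].to_numpy()

    def restrict(self, subject_ids: Iterable) -> "TrajectoryPanel":
        keep = set(subject_ids)
        sub = self._df[self._df["subject_id"].isin(keep)]
        if len(sub) == 0:
            raise PanelError("no records after restriction")
        return TrajectoryPanel(sub)

    def to_csv(self, path) -> None:
        self._df.rename(
            columns={"subject_id": "subject_id", "age": "age_years", "value": "value"}
        ).to_csv(path, index=False)


class BaselineTable:
    """Per-subject baseline covariates: sex, exposures, confounders, flags."""

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        if "subject_id" in df.columns:
            df = df.set_index("subject_id")
        if df.index.has_duplicates:
            raise PanelError("duplicate subject_id in baseline table")
        if "sex" in df.columns:
            bad = set(df["sex"].dropna().unique()) - {"male", "female"}
            if bad:
                raise PanelError(f"unrecognised sex values: {sorted(bad)}")
        self._df = df.sort_index()

    @property
    def table(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def subjects(self) -> list:
        return list(self._df.index)

    def __len__(self) -> int:
        return len(self._df)

    def column(self, name: str) -> pd.Series:
        if name not in self._df.columns:
            raise ConfigError(f"baseline column {name!r} not found")
        return self._df[name]

    def restrict(self, subject_ids: Iterable) -> "BaselineTable":
        keep = [s for s in self._df.index if s in set(subject_ids)]
        return BaselineTable(self._df.loc[keep])

    def to_csv(self, path) -> None:
        self._df.to_csv(path, index=True, index_label="subject_id")


def read_long_panel(path, column_map: Mapping[str, str] | None = None) -> TrajectoryPanel:
    """Read a tidy CSV (one row per subject-visit) into a TrajectoryPanel.

    ``column_map`` maps the canonical names ``subject_id``, ``age``, ``value``
    to the file's column names; defaults to ``subject_id, age_years, value``.
    """
    cmap = {"subject_id": "subject_id", "age": "age_years", "value": "value"}
    if column_map:
        cmap.update(column_map)
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise PanelError("no records") from None
    missing = [v for v in cmap.values() if v not in raw.columns]
    if missing:
        raise ConfigError(f"missing column(s) {missing} in {path}")
    df = raw.rename(columns={v: k for k, v in cmap.items()})
    return TrajectoryPanel(df)


def read_baseline_table(path, column_map: Mapping[str, str] | None = None) -> BaselineTable:
    raw = pd.read_csv(path)
    if column_map:
        missing = [v for v in column_map.values() if v not in raw.columns]
        if missing:
            raise ConfigError(f"missing column(s) {missing} in {path}")
        raw = raw.rename(columns={v: k for k, v in column_map.items()})
    if "subject_id" not in raw.columns:
        raise ConfigError(f"missing column(s) ['subject_id'] in {path}")
    return BaselineTable(raw)


def compute_bmi(weight_kg, height_m):
    """Body mass index: weight (kg) divided by height (m) squared."""
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise ValueError("weight and height must be strictly positive")
    out = w / h**2
    return float(out) if out.ndim == 0 else out


def preprocess_exposure(conc, spec: ExposureSpec) -> float:
    """log10-transform a concentration; below-LOD values are set to LOD/2.

    ``conc`` may be ``None`` or NaN to mark a below-LOD measurement.
    """
    below = conc is None or (isinstance(conc, float) and math.isnan(conc))
    if below:
        if spec.lod is None:
            raise ValueError(f"below-LOD value for {spec.name!r} but no LOD configured")
        return math.log10(spec.lod / 2.0)
    conc = float(conc)
    if conc < 0:
        raise ValueError(f"negative concentration {conc} for {spec.name!r}")
    if conc == 0.0:
        raise ValueError(
            f"zero concentration for {spec.name!r}: log10 undefined; "
            "encode below-LOD values as missing"
        )
    return math.log10(conc)


def preprocess_exposure_series(values: pd.Series, spec: ExposureSpec) -> pd.Series:
    """Vectorised :func:`preprocess_exposure` over a baseline column."""
    return values.map(lambda v: preprocess_exposure(v, spec))


def filter_min_visits(panel: TrajectoryPanel, min_visits: int = 4) -> TrajectoryPanel:
    """Keep subjects with at least ``min_visits`` observed visits (idempotent)."""
    if min_visits < 1:
        raise ValueError("min_visits must be >= 1")
    counts = panel.visit_counts()
    keep = counts.index[counts >= min_visits]
    if len(keep) == 0:
        raise PanelError(f"no subject has >= {min_visits} visits")
    if len(keep) == panel.n_subjects:
        return panel
    return panel.restrict(keep)


def stratify(
    panel: TrajectoryPanel,
    baseline: BaselineTable,
    by: str = "sex",
) -> list[tuple[str, TrajectoryPanel, BaselineTable]]:
    """Partition by sex, or filter by a sensitivity rule.

    ``by='sex'`` partitions subjects into (female, male) strata whose union is
    the input set.  ``by='exclude_preterm'`` / ``'exclude_low_birth_weight'``
    return a single filtered stratum dropping flagged subjects.
    """
    missing = [s for s in panel.subjects if s not in set(baseline.subjects)]
    if missing:
        raise PanelError(f"panel subjects missing from baseline table: {missing[:5]}")
    if by == "sex":
        sex = baseline.column("sex")
        out = []
        for label in ("female", "male"):
            ids = [s for s in panel.subjects if sex.get(s) == label]
            if ids:
                out.append((label, panel.restrict(ids), baseline.restrict(ids)))
        return out
    if by in SUBSET_RULES:
        flag = "preterm" if by == "exclude_preterm" else "low_birth_weight"
        flags = baseline.column(flag).astype(bool)
        ids = [s for s in panel.subjects if not flags.get(s, False)]
        if len(ids) == panel.n_subjects:
            return [(by, panel, baseline)]
        return [(by, panel.restrict(ids), baseline.restrict(ids))]
    raise ConfigError(f"unknown stratification rule {by!r}")
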