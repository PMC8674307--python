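"""Core domain containers for multi-site functional-connectivity harmonization.

The central currency is the :class:`FCFeatureTable`: an ``n_subjects x V``
matrix of Fisher-z connectivity values, where ``V = R(R-1)/2`` enumerates the
upper triangle of an ``R x R`` correlation matrix in row-major order
(0-based, ``a < b``, diagonal excluded -- Fisher z of a unit correlation is
infinite, so the diagonal is never stored).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIAGNOSIS_CODES = {"control": 0, "patient": 1}
SEX_CODES = {"male": 0, "female": 1}


def upper_triangle_pairs(n_regions: int) -> list[tuple[int, int]]:
    """Canonical feature order: row-major upper triangle, 0-based, a < b."""
    if n_regions < 2:
        raise ValueError(f"need at least 2 regions, got {n_regions}")
    return [(a, b) for a in range(n_regions) for b in range(a + 1, n_regions)]


def n_features(n_regions: int) -> int:
    return n_regions * (n_regions - 1) // 2


def pair_to_index(a: int, b: int, n_regions: int) -> int:
    """Position of ROI pair (a, b), a < b, in the canonical feature order."""
    if not (0 <= a < b < n_regions):
        raise ValueError(f"invalid ROI pair ({a}, {b}) for R={n_regions}")
    # offset of row a = sum_{k<a} (R-1-k), then column offset within row a
    return a * (2 * n_regions - a - 1) // 2 + (b - a - 1)


def index_to_pair(v: int, n_regions: int) -> tuple[int, int]:
    if not 0 <= v < n_features(n_regions):
        raise ValueError(f"feature index {v} out of range for R={n_regions}")
    a = 0
    offset = 0
    while offset + (n_regions - a - 1) <= v:
        offset += n_regions - a - 1
        a += 1
    return a, v - offset + a + 1


@dataclass
class ROITimeSeries:
    """One subject's T x R regional signal table (arbitrary BOLD-derived units)."""

    subject_id: str
    values: np.ndarray
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x R) array")
        # T >= 3 is required for Pearson FC and enforced by compute_fc and the
        # reader; the container itself permits shorter series (e.g. toy draws).
        if not np.all(np.isfinite(self.values)):
            t, r = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"subject {self.subject_id!r}: non-finite value at row {t}, column {r}"
            )
        if self.region_labels is not None and len(self.region_labels) != self.values.shape[1]:
            raise ValueError("region_labels length does not match number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class FCMatrix:
    """Symmetric R x R Pearson correlation matrix with unit diagonal."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = self.values
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12, rtol=0):
            raise ValueError("FC matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12, rtol=0):
            raise ValueError("FC matrix diagonal must be exactly 1")
        if np.any(np.abs(m) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class PhenotypeTable:
    """Per-subject site, diagnosis, age and sex, row-aligned with feature tables.

    ``diagnosis`` is coded control=0 / patient=1 and ``sex`` male=0 / female=1;
    the coding fixes the sign convention of fitted coefficients.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["subject_id", "site", "diagnosis", "age", "sex"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        dup = self.data["subject_id"][self.data["subject_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate subject_id: {sorted(set(dup))}")
        if self.data[["age", "sex", "diagnosis"]].isna().any().any():
            raise ValueError("missing age/sex/diagnosis values are not allowed")
        bad = set(self.data["diagnosis"].unique()) - {0, 1}
        if bad:
            raise ValueError(f"diagnosis codes must be 0 (control) / 1 (patient), got {bad}")
        bad = set(self.data["sex"].unique()) - {0, 1}
        if bad:
            raise ValueError(f"sex codes must be 0 (male) / 1 (female), got {bad}")
        self.data = self.data.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return self.data["subject_id"].tolist()

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def sites(self) -> list[str]:
        return sorted(self.data["site"].astype(str).unique())

    def site_labels(self) -> np.ndarray:
        return self.data["site"].astype(str).to_numpy()

    def age(self) -> np.ndarray:
        return self.data["age"].to_numpy(dtype=float)

    def sex(self) -> np.ndarray:
        return self.data["sex"].to_numpy(dtype=float)

    def diagnosis(self) -> np.ndarray:
        return self.data["diagnosis"].to_numpy(dtype=int)


@dataclass
class FCFeatureTable:
    """Subjects x FC-feature matrix of Fisher-z connectivity values.

    ``provenance`` records the ordered transforms already applied (for example
    ``["fisher_z", "residualized", "swd"]``) so that pipelines can enforce
    stage order and refuse to double-apply a harmonization.
    """

    subject_ids: list[str]
    feature_pairs: list[tuple[int, int]]
    values: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature table values must be 2-D (subjects x features)")
        if self.values.shape != (len(self.subject_ids), len(self.feature_pairs)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.feature_pairs)} features"
            )
        self.feature_pairs = [(int(a), int(b)) for a, b in self.feature_pairs]
        for a, b in self.feature_pairs:
            if not a < b:
                raise ValueError(f"feature pair ({a}, {b}) must satisfy a < b")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature_names(self) -> list[str]:
        return [f"{a}_{b}" for a, b in self.feature_pairs]

    def pair_column(self, a: int, b: int) -> int:
        try:
            return self.feature_pairs.index((a, b))
        except ValueError:
            raise KeyError(
                f"ROI pair ({a}, {b}) not in feature index; valid pairs: "
                f"{self.feature_pairs[:10]}{'...' if self.n_features > 10 else ''}"
            ) from None

    def with_values(self, values: np.ndarray, step: str | None = None) -> "FCFeatureTable":
        """Copy with new values and (optionally) one more provenance entry."""
        prov = list(self.provenance) + ([step] if step else [])
        return FCFeatureTable(list(self.subject_ids), list(self.feature_pairs), values, prov)

    def check_aligned(self, phenotypes: PhenotypeTable) -> None:
        if self.subject_ids != phenotypes.subject_ids:
            raise ValueError("feature table subject order does not match phenotype table")


@dataclass
class HarmonizationResult:
    """Harmonized table plus the method's estimated parameters for inspection."""

    table: FCFeatureTable
    method: str
    parameters: dict

    def __post_init__(self) -> None:
        if self.method not in {"swd", "glm", "combat"}:
            raise ValueError(f"unknown harmonization method {self.method!r}")
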