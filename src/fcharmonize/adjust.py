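"""OLS residualization of nuisance covariates (age, sex) from FC features.

Each feature is regressed on an intercept, age and sex; the returned values
are the residuals with the fitted intercept added back, so the harmonized
connectivity keeps its physical level while being orthogonal to the nuisance
covariates. ``keep_level=False`` returns pure residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import FCFeatureTable, PhenotypeTable


@dataclass
class DesignMatrix:
    """Named n x p design; full column rank is enforced at construction."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("design values must be n x p with one name per column")
        rank = np.linalg.matrix_rank(self.values)
        if rank < len(self.names):
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < {len(self.names)} columns: "
                f"{self.names})"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


def build_design(
    phenotypes: PhenotypeTable,
    covariates: tuple[str, ...] = ("age", "sex"),
    include_site: bool = False,
    include_diagnosis: bool = False,
) -> DesignMatrix:
    """Intercept + requested covariate columns (+ reference-coded site indicators).

    Site indicators drop the first site (sorted order) as reference level.
    """
    names = ["intercept"]
    cols = [np.ones(phenotypes.n_subjects)]
    for cov in covariates:
        if cov == "age":
            cols.append(phenotypes.age())
        elif cov == "sex":
            cols.append(phenotypes.sex())
        else:
            raise ValueError(f"unknown covariate {cov!r}")
        names.append(cov)
    if include_diagnosis:
        names.append("diagnosis")
        cols.append(phenotypes.diagnosis().astype(float))
    if include_site:
        labels = phenotypes.site_labels()
        for site in phenotypes.sites[1:]:
            names.append(f"site[{site}]")
            cols.append((labels == site).astype(float))
    return DesignMatrix(names, np.column_stack(cols))


def ols_fit(design: DesignMatrix, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients (p x V) for all features simultaneously."""
    beta, *_ = np.linalg.lstsq(design.values, y, rcond=None)
    return beta


def residualize(
    table: FCFeatureTable,
    design: DesignMatrix,
    keep_level: bool = True,
) -> FCFeatureTable:
    """Remove the design's fit from every feature.

    With ``keep_level=True`` (default) the fitted intercept is added back, so
    only covariate-driven variation is removed. The residual component is
    orthogonal to every design column either way. Idempotent.
    """
    if design.n != table.n_subjects:
        raise ValueError("design rows do not match feature-table rows")
    if table.n_subjects <= len(design.names):
        raise ValueError(
            f"need more subjects ({table.n_subjects}) than design columns ({len(design.names)})"
        )
    beta = ols_fit(design, table.values)
    resid = table.values - design.values @ beta
    if keep_level:
        if "intercept" not in design.names:
            raise ValueError("keep_level requires an intercept column")
        resid = resid + beta[design.names.index("intercept")]
    return table.with_values(resid, "residualized")


def residualize_age_sex(
    table: FCFeatureTable, phenotypes: PhenotypeTable, keep_level: bool = True
) -> FCFeatureTable:
    """Convenience wrapper: regress out age and sex (intercept retained by default)."""
    table.check_aligned(phenotypes)
    return residualize(table, build_design(phenotypes, ("age", "sex")), keep_level)
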