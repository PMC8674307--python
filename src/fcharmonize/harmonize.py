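"""Site-effect mitigation methods for multi-site FC feature tables.

Three methods operate on Fisher-z, covariate-residualized feature tables:

* :func:`swd` -- site-wise de-meaning, the simplest possible harmonization:
  one scalar mean of *all* FC values per site is subtracted from every value
  of every subject at that site. It removes the common (across-feature)
  component of a site's offset while leaving per-feature group contrasts
  untouched within each site.

* :func:`glm_remove_site` -- per-feature OLS on age, sex and reference-coded
  site indicators, subtracting either the full fitted value (default, the
  model ``y - alpha - X beta``) or only the site-indicator component
  (``mode="site-only"``).

* :func:`combat` -- parametric empirical-Bayes location/scale harmonization:
  per-feature standardization, per-site location (gamma) and scale (delta^2)
  estimates shrunk toward cross-feature moment-matched priors (normal prior
  for location, inverse-gamma for scale), followed by the standard
  ``(z - gamma*) / delta*`` adjustment rescaled to the original units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .adjust import DesignMatrix, build_design, residualize_age_sex
from .datatypes import FCFeatureTable, HarmonizationResult, PhenotypeTable


@dataclass
class SiteGrouping:
    """Per-subject site labels resolved to index lists and counts."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(str)
        if self.labels.size == 0:
            raise ValueError("empty site grouping")
        self.sites = sorted(set(self.labels.tolist()))
        self.indices = {s: np.flatnonzero(self.labels == s) for s in self.sites}
        self.counts = {s: len(self.indices[s]) for s in self.sites}
        if any(n == 0 for n in self.counts.values()):
            raise ValueError("empty site")

    @classmethod
    def from_phenotypes(cls, phenotypes: PhenotypeTable) -> "SiteGrouping":
        return cls(phenotypes.site_labels())

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def swd(table: FCFeatureTable, sites: SiteGrouping) -> HarmonizationResult:
    """Site-wise de-meaning: subtract each site's single scalar FC mean.

    The mean is taken over all subjects and all features of the site, so
    within-site group differences (and hence single-site effect sizes) are
    bit-invariant.
    """
    if len(sites.labels) != table.n_subjects:
        raise ValueError("site labels do not match feature-table rows")
    for site, n in sites.counts.items():
        if n == 1:
            warnings.warn(
                f"site {site!r} has a single subject; its SWD mean is degenerate",
                stacklevel=2,
            )
    out = table.values.copy()
    site_means: dict[str, float] = {}
    for site, idx in sites.indices.items():
        m = float(table.values[idx].mean())
        site_means[site] = m
        out[idx] -= m
    result = table.with_values(out, "swd")
    return HarmonizationResult(result, "swd", {"site_means": site_means})


def glm_remove_site(
    table: FCFeatureTable,
    phenotypes: PhenotypeTable,
    mode: str = "full",
) -> HarmonizationResult:
    """Per-feature OLS on age, sex and site indicators; subtract the fit.

    ``mode="full"`` subtracts the entire fitted value (intercept, age, sex and
    site components): the output is the OLS residual, orthogonal to every
    design column. ``mode="site-only"`` subtracts only the site-indicator
    component, leaving level and covariate structure intact.
    """
    if mode not in {"full", "site-only"}:
        raise ValueError(f"unknown GLM mode {mode!r}")
    table.check_aligned(phenotypes)
    design = build_design(phenotypes, ("age", "sex"), include_site=True)
    beta, *_ = np.linalg.lstsq(design.values, table.values, rcond=None)
    if mode == "full":
        out = table.values - design.values @ beta
    else:
        site_cols = [j for j, name in enumerate(design.names) if name.startswith("site[")]
        out = table.values - design.values[:, site_cols] @ beta[site_cols]
    params = {
        "design_columns": design.names,
        "alpha": beta[design.names.index("intercept")],
        "beta": beta,
        "mode": mode,
    }
    return HarmonizationResult(table.with_values(out, f"glm_{mode}"), "glm", params)


def combat(
    table: FCFeatureTable,
    sites: SiteGrouping,
    phenotypes: PhenotypeTable,
    covariates: tuple[str, ...] = ("age", "sex"),
    include_diagnosis: bool = True,
    regress_age_sex_after: bool = True,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> HarmonizationResult:
    """Parametric empirical-Bayes ComBat harmonization.

    Steps:

    1. Per feature, OLS with one indicator per site plus the biological
       covariates (age, sex and -- by default -- diagnosis, the covariate of
       interest that harmonization must protect). The per-site intercepts
       gamma_hat are re-expressed about their sample-size-weighted mean
       alpha_hat, which enforces ``sum_i n_i gamma_i = 0``; the pooled
       variance is the mean squared residual of the full fit.
    2. Standardize: ``z = (y - alpha_hat - X beta_hat) / sigma_hat``.
    3. Per site, method-of-moments hyperpriors across features (normal for
       location, inverse-gamma for scale) and iterated conditional EB updates
       of gamma* and delta^2* until the largest absolute change is <= tol.
    4. Adjust ``y* = sigma_hat (z - gamma*) / delta* + alpha_hat + X beta_hat``.

    Afterwards (``regress_age_sex_after=True``, matching the study pipeline)
    age and sex are regressed out of the harmonized table again.
    """
    table.check_aligned(phenotypes)
    if len(sites.labels) != table.n_subjects:
        raise ValueError("site labels do not match feature-table rows")
    for site, n in sites.counts.items():
        if n < 2:
            raise ValueError(f"ComBat requires at least 2 subjects per site; site {site!r} has {n}")

    y = table.values
    n, n_feat = y.shape
    site_order = sites.sites
    n_i = np.array([sites.counts[s] for s in site_order], dtype=float)

    # step 1: one-hot site design plus covariates (no global intercept)
    onehot = np.column_stack(
        [(sites.labels == s).astype(float) for s in site_order]
    )
    cov_names: list[str] = list(covariates) + (["diagnosis"] if include_diagnosis else [])
    cov_cols = []
    for name in cov_names:
        col = {"age": phenotypes.age, "sex": phenotypes.sex}.get(name)
        cov_cols.append(col() if col else phenotypes.diagnosis().astype(float))
    cov = np.column_stack(cov_cols) if cov_cols else np.empty((n, 0))
    design = np.hstack([onehot, cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "ComBat design is rank deficient (a covariate is confounded with site)"
        )
    b_hat, *_ = np.linalg.lstsq(design, y, rcond=None)
    site_coef = b_hat[: len(site_order)]           # S x V per-site intercepts
    beta_cov = b_hat[len(site_order):]             # q x V covariate effects
    alpha_hat = (n_i / n) @ site_coef              # weighted grand intercept, 1 x V
    fit_cov = cov @ beta_cov if cov.shape[1] else 0.0
    var_pooled = ((y - design @ b_hat) ** 2).mean(axis=0)
    if np.any(var_pooled <= 0):
        raise ValueError("a feature has zero pooled residual variance")
    sigma = np.sqrt(var_pooled)

    # step 2: standardize
    z = (y - alpha_hat - fit_cov) / sigma

    # step 3: per-site EB shrinkage
    gamma_hat = np.vstack([z[sites.indices[s]].mean(axis=0) for s in site_order])
    delta_hat_sq = np.vstack([z[sites.indices[s]].var(axis=0, ddof=1) for s in site_order])
    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1)
    m = delta_hat_sq.mean(axis=1)
    s2 = delta_hat_sq.var(axis=1, ddof=1)
    lam = (m**2 + 2 * s2) / s2                     # inverse-gamma shape
    theta = (m**3 + m * s2) / s2                   # inverse-gamma scale

    gamma_star = gamma_hat.copy()
    delta_star_sq = delta_hat_sq.copy()
    iterations: dict[str, int] = {}
    for k, site in enumerate(site_order):
        zi = z[sites.indices[site]]
        ni = n_i[k]
        g, d = gamma_hat[k].copy(), delta_hat_sq[k].copy()
        for it in range(1, max_iter + 1):
            g_new = (ni * tau_sq[k] * gamma_hat[k] + d * gamma_bar[k]) / (
                ni * tau_sq[k] + d
            )
            sum2 = ((zi - g_new) ** 2).sum(axis=0)
            d_new = (theta[k] + 0.5 * sum2) / (ni / 2 + lam[k] - 1)
            change = max(np.abs(g_new - g).max(), np.abs(d_new - d).max())
            g, d = g_new, d_new
            if change <= tol:
                break
        else:
            raise RuntimeError(
                f"ComBat EB iteration did not converge for site {site!r} after "
                f"{max_iter} iterations (last max change {change:.3e})"
            )
        iterations[site] = it
        gamma_star[k], delta_star_sq[k] = g, d

    # step 4: adjust back to the original units
    site_index = np.array([site_order.index(s) for s in sites.labels])
    z_adj = (z - gamma_star[site_index]) / np.sqrt(delta_star_sq[site_index])
    out = sigma * z_adj + alpha_hat + fit_cov

    result_table = table.with_values(out, "combat")
    params = {
        "site_order": site_order,
        "alpha": alpha_hat,
        "beta_cov": beta_cov,
        "covariate_names": cov_names,
        "sigma": sigma,
        "gamma_hat": gamma_hat,
        "delta_hat_sq": delta_hat_sq,
        "gamma_star": gamma_star,
        "delta_star_sq": delta_star_sq,
        "gamma_bar": gamma_bar,
        "tau_sq": tau_sq,
        "lambda": lam,
        "theta": theta,
        "iterations": iterations,
    }
    if regress_age_sex_after:
        result_table = residualize_age_sex(result_table, phenotypes)
    return HarmonizationResult(result_table, "combat", params)


def harmonize(
    table: FCFeatureTable,
    phenotypes: PhenotypeTable,
    method: str,
    glm_mode: str = "full",
    **combat_kwargs,
) -> HarmonizationResult:
    """Dispatch to one of the three methods by name."""
    table.check_aligned(phenotypes)
    if method == "swd":
        return swd(table, SiteGrouping.from_phenotypes(phenotypes))
    if method == "glm":
        return glm_remove_site(table, phenotypes, mode=glm_mode)
    if method == "combat":
        return combat(
            table, SiteGrouping.from_phenotypes(phenotypes), phenotypes, **combat_kwargs
        )
    raise ValueError(f"unknown harmonization method {method!r}")
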