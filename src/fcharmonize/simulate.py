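"""Synthetic multi-site FC cohorts with known site, covariate and diagnosis effects.

The generator mirrors the location/scale model that the harmonization methods
assume on the Fisher-z scale:

    y_ijv = alpha_v + age_ij * beta_age_v + sex_ij * beta_sex_v
            + diagnosis_ij * shift_v + gamma_iv + delta_iv * eps_ijv,

with eps ~ Normal(0, noise_sd), additive site effects gamma_iv ~
Normal(Gamma_i, tau^2) around a per-site common offset Gamma_i ~
Normal(0, site_sd^2), and multiplicative site effects delta_iv that are 1 by
default or drawn from a unit-mean inverse-gamma. The diagnosis effect is
specified in within-group SD units and applied as patient *hypo*connectivity
(patients shifted down by d * noise_sd on the designated signal features), so
Hedges' g = (M_control - M_patient)/SD is positive on signal features.

Random streams are split per conceptual draw (phenotypes, parameters, noise)
so changing one configuration field does not perturb unrelated draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import (
    FCFeatureTable,
    PhenotypeTable,
    ROITimeSeries,
    n_features as v_of_r,
    upper_triangle_pairs,
)


@dataclass
class SimulationConfig:
    """Generating parameters of a synthetic multi-site cohort (Fisher-z scale).

    Defaults are a desk-scale 4-site cohort (n_i alternating 40/60, R=20 so
    V=190) with site offsets about half the between-subject noise SD and a
    medium diagnosis effect on one signal feature.
    """

    site_names: tuple[str, ...] = ("siteA", "siteB", "siteC", "siteD")
    n_per_site: tuple[int, ...] = (40, 60, 40, 60)
    patient_frac: tuple[float, ...] = (0.5, 0.5, 0.5, 0.5)
    n_regions: int | None = 20
    n_feat: int | None = None            # overrides n_regions when set
    alpha_mean: float = 0.25             # typical Fisher-z FC level
    alpha_sd: float = 0.15
    beta_age_sd: float = 0.002           # per-year covariate effect scale
    beta_sex_sd: float = 0.02
    d: float = 0.5                       # diagnosis effect, within-group SD units
    n_signal: int = 1
    site_sd: float = 0.1                 # SD of the common per-site offset Gamma_i
    tau: float = 0.05                    # per-feature spread of gamma_iv about Gamma_i
    delta_sd: float = 0.0                # 0 -> delta = 1; >0 -> unit-mean inverse gamma
    noise_sd: float = 0.2                # between-subject SD of z-FC
    age_mean: tuple[float, ...] = (30.0, 30.0, 30.0, 30.0)
    age_sd: tuple[float, ...] = (10.0, 10.0, 10.0, 10.0)
    male_frac: tuple[float, ...] = (0.5, 0.5, 0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        n_sites = len(self.site_names)
        for name in ("n_per_site", "patient_frac", "age_mean", "age_sd", "male_frac"):
            if len(getattr(self, name)) != n_sites:
                raise ValueError(f"{name} must have one entry per site ({n_sites})")
        if any(n <= 0 for n in self.n_per_site):
            raise ValueError("all site sizes must be positive")
        if any(not 0 <= p <= 1 for p in self.patient_frac):
            raise ValueError("patient fractions must lie in [0, 1]")
        if self.n_feat is None and self.n_regions is None:
            raise ValueError("specify n_regions or n_feat")

    @property
    def n_features(self) -> int:
        return self.n_feat if self.n_feat is not None else v_of_r(self.n_regions)

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_site))


@dataclass
class SimulationTruth:
    """Drawn generating parameters; reconstructs the noiseless expectation."""

    alpha: np.ndarray
    beta_age: np.ndarray
    beta_sex: np.ndarray
    signal_indices: np.ndarray
    patient_shift: np.ndarray        # additive term for patients, per feature
    gamma_site: np.ndarray           # common per-site offsets Gamma_i
    gamma: np.ndarray                # S x V additive site effects
    delta: np.ndarray                # S x V multiplicative site effects
    noise_sd: float
    seed: int
    config: dict = field(default_factory=dict)

    def expected(self, phenotypes: PhenotypeTable, site_order: list[str]) -> np.ndarray:
        """Noiseless expectation of every cell, for parameter-recovery checks."""
        site_idx = np.array([site_order.index(s) for s in phenotypes.site_labels()])
        return (
            self.alpha
            + np.outer(phenotypes.age(), self.beta_age)
            + np.outer(phenotypes.sex(), self.beta_sex)
            + np.outer(phenotypes.diagnosis(), self.patient_shift)
            + self.gamma[site_idx]
        )


def bsnip_like_config(**overrides) -> SimulationConfig:
    """A 4-site cohort mirroring a published schizophrenia consortium's
    demography: site sizes 188/52/143/129, patient fractions 0.59-0.71,
    per-site age means 34-40 years, near-balanced sex."""
    params = dict(
        site_names=("Baltimore", "Boston", "Dallas", "Hartford"),
        n_per_site=(188, 52, 143, 129),
        patient_frac=(0.713, 0.654, 0.594, 0.705),
        age_mean=(38.7, 34.7, 39.6, 33.9),
        age_sd=(12.7, 11.5, 11.4, 11.3),
        male_frac=(0.528, 0.500, 0.441, 0.519),
    )
    params.update(overrides)
    return SimulationConfig(**params)


def simulate_features(
    config: SimulationConfig,
) -> tuple[FCFeatureTable, PhenotypeTable, SimulationTruth]:
    """Draw a cohort: feature table (Fisher-z scale), phenotypes and truth."""
    pheno_ss, param_ss, noise_ss = np.random.SeedSequence(config.seed).spawn(3)
    pheno_rng = np.random.default_rng(pheno_ss)
    param_rng = np.random.default_rng(param_ss)
    noise_rng = np.random.default_rng(noise_ss)

    # phenotypes, site by site
    records = []
    for i, site in enumerate(config.site_names):
        ni = config.n_per_site[i]
        age = pheno_rng.normal(config.age_mean[i], config.age_sd[i], ni)
        sex = (pheno_rng.random(ni) >= config.male_frac[i]).astype(int)  # male=0
        diag = (pheno_rng.random(ni) < config.patient_frac[i]).astype(int)
        for j in range(ni):
            records.append(
                {
                    "subject_id": f"{site}-{j:04d}",
                    "site": site,
                    "diagnosis": int(diag[j]),
                    "age": float(age[j]),
                    "sex": int(sex[j]),
                }
            )
    phenotypes = PhenotypeTable(pd.DataFrame(records))

    # generating parameters
    n_sites, V = len(config.site_names), config.n_features
    alpha = param_rng.normal(config.alpha_mean, config.alpha_sd, V)
    beta_age = param_rng.normal(0.0, config.beta_age_sd, V)
    beta_sex = param_rng.normal(0.0, config.beta_sex_sd, V)
    signal = np.sort(param_rng.choice(V, size=config.n_signal, replace=False))
    patient_shift = np.zeros(V)
    patient_shift[signal] = -config.d * config.noise_sd  # hypoconnectivity
    gamma_site = param_rng.normal(0.0, config.site_sd, n_sites)
    gamma = param_rng.normal(gamma_site[:, None], config.tau, (n_sites, V))
    if config.delta_sd > 0:
        # unit-mean inverse gamma: shape a = 2 + 1/sd^2, scale b = a - 1
        a = 2.0 + 1.0 / config.delta_sd**2
        delta = (a - 1.0) / param_rng.gamma(a, 1.0, (n_sites, V))
    else:
        delta = np.ones((n_sites, V))

    truth = SimulationTruth(
        alpha, beta_age, beta_sex, signal, patient_shift, gamma_site, gamma, delta,
        config.noise_sd, config.seed, asdict(config),
    )
    site_order = list(config.site_names)
    eps = noise_rng.normal(0.0, config.noise_sd, (config.n_subjects, V))
    site_idx = np.array([site_order.index(s) for s in phenotypes.site_labels()])
    values = truth.expected(phenotypes, site_order) + delta[site_idx] * eps

    pairs = (
        upper_triangle_pairs(config.n_regions)
        if config.n_feat is None
        else [(0, v + 1) for v in range(V)]  # synthetic index when V is given directly
    )
    table = FCFeatureTable(
        phenotypes.subject_ids, pairs[:V], values, provenance=["fisher_z"]
    )
    return table, phenotypes, truth


def simulate_timeseries(
    target_corr: np.ndarray,
    n_timepoints: int,
    subject_ids: list[str],
    seed: int = 0,
) -> list[ROITimeSeries]:
    """Zero-mean multivariate-normal time series with a target correlation.

    The empirical FC of each subject converges to ``target_corr`` as the
    number of timepoints grows. The target must be positive definite.
    """
    target = np.asarray(target_corr, dtype=float)
    if target.ndim != 2 or target.shape[0] != target.shape[1]:
        raise ValueError("target correlation must be square")
    if not np.allclose(target, target.T, atol=1e-10):
        raise ValueError("target correlation must be symmetric")
    try:
        chol = np.linalg.cholesky(target)
    except np.linalg.LinAlgError:
        raise ValueError("target correlation matrix is not positive definite") from None
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = []
    for sid in subject_ids:
        draws = rng.standard_normal((n_timepoints, target.shape[0])) @ chol.T
        out.append(ROITimeSeries(sid, draws))
    return out


def truth_frame(truth: SimulationTruth, site_order: list[str]) -> pd.DataFrame:
    """Flat per-feature view of the truth (for writing alongside a cohort)."""
    V = len(truth.alpha)
    data = {
        "feature": np.arange(V),
        "alpha": truth.alpha,
        "beta_age": truth.beta_age,
        "beta_sex": truth.beta_sex,
        "patient_shift": truth.patient_shift,
        "is_signal": np.isin(np.arange(V), truth.signal_indices).astype(int),
    }
    for i, site in enumerate(site_order):
        data[f"gamma[{site}]"] = truth.gamma[i]
        data[f"delta[{site}]"] = truth.delta[i]
    return pd.DataFrame(data)
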