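import numpy as np
import pytest

from fcharmonize import SiteGrouping, combat
from fcharmonize.simulate import SimulationConfig, simulate_features

from reference_combat import reference_combat


def simulate(seed=42, sites=3, n_per_site=10, V=20, **kw):
    params = dict(
        site_names=tuple(f"site{i}" for i in range(sites)),
        n_per_site=(n_per_site,) * sites,
        patient_frac=(0.5,) * sites,
        n_regions=None,
        n_feat=V,
        age_mean=(30.0,) * sites,
        age_sd=(10.0,) * sites,
        male_frac=(0.5,) * sites,
        seed=seed,
    )
    params.update(kw)
    return simulate_features(SimulationConfig(**params))


def test_combat_matches_independent_reference():
    """Small instance (3 sites, n_i=10, V=20): per-entry agreement <= 1e-6 with
    the independently coded loop-based parametric ComBat."""
    table, pheno, _ = simulate(seed=42, site_sd=0.1, tau=0.05, delta_sd=0.3)
    result = combat(
        table, SiteGrouping.from_phenotypes(pheno), pheno, regress_age_sex_after=False
    )
    cov = np.column_stack([pheno.age(), pheno.sex(), pheno.diagnosis().astype(float)])
    expected = reference_combat(table.values, list(pheno.site_labels()), cov)
    assert np.abs(result.table.values - expected).max() <= 1e-6


def test_combat_null_site_effects_returns_data_nearly_unchanged():
    """gamma=0, delta=1: the adjustment is pure estimation noise, bounded by
    ~sigma/sqrt(n_i) per entry (RMS <= 3*noise_sd/sqrt(n_i))."""
    n_i = 100
    table, pheno, truth = simulate(
        seed=11, sites=3, n_per_site=n_i, V=200, site_sd=0.0, tau=0.0, delta_sd=0.0
    )
    result = combat(
        table, SiteGrouping.from_phenotypes(pheno), pheno, regress_age_sex_after=False
    )
    rms = np.sqrt(((result.table.values - table.values) ** 2).mean())
    assert rms <= 3 * truth.noise_sd / np.sqrt(n_i)


def test_combat_recovers_location_effects():
    """Location-only site effects (delta=1): EB estimates gamma* correlate with
    the generating gamma at r > 0.95 (n_i=50, V=500, fixed seed)."""
    table, pheno, truth = simulate(
        seed=5, sites=4, n_per_site=50, V=500, site_sd=0.15, tau=0.1, delta_sd=0.0
    )
    result = combat(
        table, SiteGrouping.from_phenotypes(pheno), pheno, regress_age_sex_after=False
    )
    p = result.parameters
    # gamma* lives on the standardized scale; compare per-site centered effects
    recovered = (p["gamma_star"] * p["sigma"]).ravel()
    n_i = np.array([50] * 4, dtype=float)
    centered_truth = truth.gamma - (n_i / n_i.sum()) @ truth.gamma
    r = np.corrcoef(recovered, centered_truth.ravel())[0, 1]
    assert r > 0.95


def test_combat_recovers_scale_effects():
    table, pheno, truth = simulate(
        seed=6, sites=4, n_per_site=50, V=500, site_sd=0.1, tau=0.05, delta_sd=0.4
    )
    result = combat(
        table, SiteGrouping.from_phenotypes(pheno), pheno, regress_age_sex_after=False
    )
    recovered = np.sqrt(result.parameters["delta_star_sq"]).ravel()
    # delta* is estimated on the standardized scale, i.e. relative to each
    # feature's pooled SD: compare against the correspondingly normalized truth
    weights = np.full(4, 50.0) / 200.0
    relative_truth = truth.delta / np.sqrt(weights @ truth.delta**2)
    r = np.corrcoef(recovered, relative_truth.ravel())[0, 1]
    assert r > 0.8


def test_combat_fixed_point_satisfies_both_updates():
    """One more application of the conditional EB updates moves gamma*, delta2*
    by no more than the convergence tolerance."""
    tol = 1e-4
    table, pheno, _ = simulate(seed=42, site_sd=0.1, tau=0.05, delta_sd=0.3)
    grouping = SiteGrouping.from_phenotypes(pheno)
    result = combat(table, grouping, pheno, regress_age_sex_after=False, tol=tol)
    p = result.parameters
    y = table.values
    z = (y - p["alpha"] - _cov_fit(pheno, p)) / p["sigma"]
    for k, site in enumerate(p["site_order"]):
        zi = z[grouping.indices[site]]
        ni = len(zi)
        g_next = (ni * p["tau_sq"][k] * p["gamma_hat"][k] + p["delta_star_sq"][k] * p["gamma_bar"][k]) / (
            ni * p["tau_sq"][k] + p["delta_star_sq"][k]
        )
        d_next = (p["theta"][k] + 0.5 * ((zi - g_next) ** 2).sum(0)) / (ni / 2 + p["lambda"][k] - 1)
        assert np.abs(g_next - p["gamma_star"][k]).max() <= tol
        assert np.abs(d_next - p["delta_star_sq"][k]).max() <= 2 * tol
        assert p["iterations"][site] >= 1


def _cov_fit(pheno, params):
    cov = np.column_stack([pheno.age(), pheno.sex(), pheno.diagnosis().astype(float)])
    return cov @ params["beta_cov"]


def test_combat_equalizes_site_means_as_n_grows():
    """Per-feature site-conditional means agree across sites after adjustment,
    with the residual gap shrinking as site size grows."""
    gaps = {}
    for n_i in (20, 200):
        table, pheno, _ = simulate(
            seed=3, sites=3, n_per_site=n_i, V=50, site_sd=0.2, tau=0.1, d=0.0
        )
        result = combat(
            table, SiteGrouping.from_phenotypes(pheno), pheno, regress_age_sex_after=False
        )
        labels = pheno.site_labels()
        means = np.vstack(
            [result.table.values[labels == s].mean(0) for s in sorted(set(labels))]
        )
        gaps[n_i] = np.abs(means.max(0) - means.min(0)).mean()
        raw_means = np.vstack(
            [table.values[labels == s].mean(0) for s in sorted(set(labels))]
        )
        raw_gap = np.abs(raw_means.max(0) - raw_means.min(0)).mean()
        assert gaps[n_i] < raw_gap  # harmonization reduces site separation
    assert gaps[200] < gaps[20]


def test_combat_rejects_single_subject_sites():
    table, pheno, _ = simulate(seed=1)
    pheno.data.loc[0, "site"] = "lonely"
    table2 = table.with_values(table.values)
    with pytest.raises(ValueError, match="at least 2"):
        combat(table2, SiteGrouping.from_phenotypes(pheno), pheno)


def test_combat_parameters_are_finite():
    table, pheno, _ = simulate(seed=9, delta_sd=0.3)
    result = combat(table, SiteGrouping.from_phenotypes(pheno), pheno)
    for key in ("alpha", "sigma", "gamma_star", "delta_star_sq", "tau_sq", "lambda", "theta"):
        assert np.all(np.isfinite(result.parameters[key])), key
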