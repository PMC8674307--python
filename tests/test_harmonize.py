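import numpy as np
import pandas as pd
import pytest

from fcharmonize import (
    FCFeatureTable,
    PhenotypeTable,
    SiteGrouping,
    glm_remove_site,
    harmonize,
    hedges_g,
    residualize_age_sex,
    swd,
)
from fcharmonize.simulate import SimulationConfig, simulate_features


def two_site_fixture(rng, n_per_site=6, n_feat=4):
    n = 2 * n_per_site
    pheno = PhenotypeTable(
        pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "site": ["A"] * n_per_site + ["B"] * n_per_site,
                "diagnosis": [0, 1] * n_per_site,
                "age": rng.uniform(20, 60, n).round(1),
                "sex": rng.integers(0, 2, n),
            }
        )
    )
    values = rng.normal(0.3, 0.2, (n, n_feat))
    table = FCFeatureTable(
        pheno.subject_ids, [(0, v + 1) for v in range(n_feat)], values, ["fisher_z"]
    )
    return table, pheno


def test_swd_hand_example():
    """One site with rows (1,3) and (2,4): scalar mean 2.5 is subtracted."""
    table = FCFeatureTable(["a", "b"], [(0, 1), (0, 2)], [[1.0, 3.0], [2.0, 4.0]])
    result = swd(table, SiteGrouping(["X", "X"]))
    assert result.parameters["site_means"] == {"X": 2.5}
    np.testing.assert_array_equal(result.table.values, [[-1.5, 0.5], [-0.5, 1.5]])


def test_swd_zeroes_every_site_grand_mean(toy_cohort):
    table, phenotypes, _ = toy_cohort
    grouping = SiteGrouping.from_phenotypes(phenotypes)
    out = swd(table, grouping).table
    for site, idx in grouping.indices.items():
        assert abs(out.values[idx].mean()) < 1e-12


def test_swd_is_idempotent(toy_cohort):
    table, phenotypes, _ = toy_cohort
    grouping = SiteGrouping.from_phenotypes(phenotypes)
    once = swd(table, grouping).table
    twice = swd(once, grouping).table
    # the second pass subtracts a residual site mean at machine-epsilon level
    np.testing.assert_allclose(twice.values, once.values, rtol=0, atol=1e-12)


def test_swd_preserves_within_site_group_contrast(rng):
    """The same scalar is subtracted from both groups, bit-for-bit."""
    table, pheno = two_site_fixture(rng)
    out = swd(table, SiteGrouping.from_phenotypes(pheno)).table
    diag, labels = pheno.diagnosis(), pheno.site_labels()
    for site in ("A", "B"):
        m = labels == site
        before = table.values[m & (diag == 0)].mean(0) - table.values[m & (diag == 1)].mean(0)
        after = out.values[m & (diag == 0)].mean(0) - out.values[m & (diag == 1)].mean(0)
        np.testing.assert_allclose(after, before, rtol=0, atol=1e-12)


def test_swd_single_site_hedges_g_invariant(rng):
    table, pheno = two_site_fixture(rng, n_per_site=12)
    one_site = PhenotypeTable(pheno.data.assign(site="only"))
    out = swd(table, SiteGrouping.from_phenotypes(one_site)).table
    diag = one_site.diagnosis()
    for v in range(table.n_features):
        g0 = hedges_g(table.values[diag == 0, v], table.values[diag == 1, v])
        g1 = hedges_g(out.values[diag == 0, v], out.values[diag == 1, v])
        assert g1 == pytest.approx(g0, abs=1e-12)


def test_swd_commutes_with_global_feature_shift(rng):
    """swd(x + c_v) = swd(x) + (c_v - mean(c)): the shift survives minus its mean."""
    table, pheno = two_site_fixture(rng)
    grouping = SiteGrouping.from_phenotypes(pheno)
    shift = rng.normal(0, 1, table.n_features)
    shifted = table.with_values(table.values + shift)
    lhs = swd(shifted, grouping).table.values
    rhs = swd(table, grouping).table.values + (shift - shift.mean())
    np.testing.assert_allclose(lhs, rhs, atol=1e-12)


def test_swd_warns_on_single_subject_site():
    table = FCFeatureTable(["a", "b"], [(0, 1)], [[1.0], [2.0]])
    with pytest.warns(UserWarning, match="single subject"):
        swd(table, SiteGrouping(["X", "Y"]))


def test_swd_empty_site_is_impossible_by_construction():
    with pytest.raises(ValueError):
        SiteGrouping(np.array([], dtype=str))


def test_glm_residuals_orthogonal_to_design(toy_cohort):
    table, phenotypes, _ = toy_cohort
    out = glm_remove_site(table, phenotypes, mode="full").table
    age, sex = phenotypes.age(), phenotypes.sex()
    labels = phenotypes.site_labels()
    for v in range(0, table.n_features, 25):
        assert abs(np.corrcoef(out.values[:, v], age)[0, 1]) < 1e-10
        assert abs(np.corrcoef(out.values[:, v], sex)[0, 1]) < 1e-10
        for site in phenotypes.sites:
            assert abs(out.values[labels == site, v].mean()) < 1e-10


def test_glm_site_only_removes_constructed_offsets_exactly(rng):
    """Noise-free site offsets + balanced group signal: site-only mode recovers
    the offsets and leaves the group signal untouched."""
    n_per_site, n_feat = 8, 3
    pheno = PhenotypeTable(
        pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(2 * n_per_site)],
                "site": ["A"] * n_per_site + ["B"] * n_per_site,
                "diagnosis": [0, 1] * n_per_site,
                "age": np.tile([20.0, 30.0, 40.0, 50.0], 4),
                "sex": [0, 1] * n_per_site,
            }
        )
    )
    offsets = {"A": 0.5, "B": -0.3}
    signal = np.array([0.0, 0.2, -0.1])
    values = np.zeros((2 * n_per_site, n_feat))
    for i in range(2 * n_per_site):
        values[i] = offsets[pheno.data.loc[i, "site"]] + pheno.data.loc[i, "diagnosis"] * signal
    table = FCFeatureTable(pheno.subject_ids, [(0, 1), (0, 2), (1, 2)], values, ["fisher_z"])
    out = glm_remove_site(table, pheno, mode="site-only").table
    # diagnosis is balanced across sites, so site indicators absorb exactly the offsets
    expected = values.copy()
    shift = {"A": 0.0, "B": offsets["B"] - offsets["A"]}  # reference-coded indicator part
    for i in range(2 * n_per_site):
        expected[i] -= shift[pheno.data.loc[i, "site"]]
    np.testing.assert_allclose(out.values, expected, atol=1e-10)
    diag = pheno.diagnosis()
    np.testing.assert_allclose(
        out.values[diag == 1].mean(0) - out.values[diag == 0].mean(0), signal, atol=1e-10
    )


def test_glm_full_equals_pure_covariate_residuals_when_no_site_effect():
    """Noise-free covariate-only data: both routes return exactly zero residuals."""
    age = np.array([20.0, 30.0, 40.0, 50.0, 25.0, 35.0, 45.0, 55.0])
    sex = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
    pheno = PhenotypeTable(
        pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(8)],
                "site": ["A"] * 4 + ["B"] * 4,
                "diagnosis": [0, 1] * 4,
                "age": age,
                "sex": sex,
            }
        )
    )
    y = 1.0 + 0.02 * age - 0.1 * sex
    table = FCFeatureTable(pheno.subject_ids, [(0, 1)], y[:, None], ["fisher_z"])
    glm_out = glm_remove_site(table, pheno, mode="full").table
    pure = residualize_age_sex(table, pheno, keep_level=False)
    np.testing.assert_allclose(glm_out.values, pure.values, atol=1e-10)
    np.testing.assert_allclose(glm_out.values, 0.0, atol=1e-10)


def test_methods_preserve_shape_and_subject_order(toy_cohort):
    table, phenotypes, _ = toy_cohort
    for method in ("swd", "glm", "combat"):
        result = harmonize(table, phenotypes, method)
        assert result.table.values.shape == table.values.shape
        assert result.table.subject_ids == table.subject_ids


def test_glm_unknown_mode_rejected(toy_cohort):
    table, phenotypes, _ = toy_cohort
    with pytest.raises(ValueError, match="mode"):
        glm_remove_site(table, phenotypes, mode="banana")


def test_glm_absorbs_group_contrast_under_imbalance():
    """Mechanism check: with diagnosis-imbalanced sites, GLM's site indicators
    absorb part of the between-group mean difference while SWD's scalar
    subtraction cannot. With purely common (across-feature) site offsets the
    paired contrast gap diff_swd - diff_glm is positive on average."""
    from fcharmonize import bsnip_like_config, ordering_replicates

    frame = ordering_replicates(100, bsnip_like_config(tau=0.0), seed=2024)
    gap = frame["diff_swd"] - frame["diff_glm"]
    t_stat = gap.mean() / (gap.std(ddof=1) / np.sqrt(len(gap)))
    assert gap.mean() > 0
    assert t_stat > 2.0
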