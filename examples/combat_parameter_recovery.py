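"""Check that ComBat's empirical-Bayes estimates recover simulated site effects.

Simulates location-shifted sites, runs ComBat, and correlates the shrunken
location estimates gamma* (rescaled to data units) with the generating
offsets. High correlation means the EB machinery identifies the right
per-site, per-feature adjustments.
"""

import numpy as np

from fcharmonize import SimulationConfig, SiteGrouping, combat, simulate_features

config = SimulationConfig(
    site_names=("a", "b", "c", "d"), n_per_site=(50,) * 4, patient_frac=(0.5,) * 4,
    n_regions=None, n_feat=500, age_mean=(30.0,) * 4, age_sd=(10.0,) * 4,
    male_frac=(0.5,) * 4, site_sd=0.15, tau=0.1, delta_sd=0.0, seed=5,
)
table, phenotypes, truth = simulate_features(config)
result = combat(
    table, SiteGrouping.from_phenotypes(phenotypes), phenotypes,
    regress_age_sex_after=False,
)
p = result.parameters
recovered = (p["gamma_star"] * p["sigma"]).ravel()
weights = np.asarray(config.n_per_site) / sum(config.n_per_site)
centered_truth = (truth.gamma - weights @ truth.gamma).ravel()
r = np.corrcoef(recovered, centered_truth)[0, 1]
print(f"location-effect recovery: r = {r:.4f} over {recovered.size} site-feature cells")
print("EB iterations per site:", p["iterations"])
# r above ~0.95 indicates the additive site effects are recovered almost
# perfectly at n_i = 50 subjects per site; the truth is centered because the
# model identifies site effects only up to their weighted mean.
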