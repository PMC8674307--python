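"""Generate a synthetic 4-site FC cohort and inspect its ground truth.

The generator draws Fisher-z connectivity features under the location/scale
site-effect model with per-site demography, so every harmonization method can
be exercised without any real imaging data.
"""

from fcharmonize import SimulationConfig, simulate_features

config = SimulationConfig(seed=11, d=0.5, site_sd=0.1, tau=0.05)
table, phenotypes, truth = simulate_features(config)

print(f"cohort: {table.n_subjects} subjects x {table.n_features} features")
print(phenotypes.data.groupby("site").agg(
    n=("subject_id", "size"), patients=("diagnosis", "sum"), mean_age=("age", "mean")
).round(1))
print("\nper-site common offsets Gamma_i:", truth.gamma_site.round(3))
print("signal feature index:", truth.signal_indices, "patient shift:",
      truth.patient_shift[truth.signal_indices])
# Gamma_i are the additive site offsets every harmonization method must remove;
# the patient shift is the diagnosis effect they must preserve.
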