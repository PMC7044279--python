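"""Generate a synthetic AML-like survival cohort and inspect its structure.

A latent disease-state level z per patient drives one biomarker probe, a
proportional-hazards survival disadvantage, mutation-like confounders and a
co-expressed 30-gene module; everything else is noise.
"""

import survscreen as ss

spec = ss.SyntheticCohortSpec(n_probes=500, seed=7)
matrix, clinical, truth = ss.generate_cohort(spec)

print(f"cohort: {spec.n_patients} patients x {spec.n_probes} probes")
print(f"planted biomarker: {truth.biomarker_probe}; module genes: {len(truth.module_probes)}")
print(f"censoring fraction (OS): {1 - clinical.data['os_event'].mean():.2f}")

z = truth.z
low_third = z[z <= z.quantile(1 / 3)].index
high_third = z[z >= z.quantile(2 / 3)].index
carriers = clinical.data["NPM1c_like"] == "yes"
print(
    "NPM1c-like prevalence, low vs high latent tertile: "
    f"{carriers[low_third].mean():.2f} vs {carriers[high_third].mean():.2f}"
)
print("-> the confounder tracks disease state, so biomarker subgroups will inherit it")
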