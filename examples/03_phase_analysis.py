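"""Phase-domain analysis: cardiac phase of each endpoint and circular stats.

Simulates a cohort with a weak von Mises phase preference (mu = 81 degrees,
kappa = 0.5) injected into the executing subject's cardiac cycle, then runs
the phase pipeline: per-event phase (t_e - prev R)/T_R * 360, per-subject
circular means, a group Rayleigh test on those means, and per-bin t-tests of
the smoothed 20-bin histograms against the uniform expectation 0.05.
"""

from cardiomotor import SimulationConfig, analyze_dataset
from cardiomotor.simulate import generate_cohort

config = SimulationConfig(coupling_mode="von_mises", mu=81.0, kappa=0.5)
dataset, subjects = generate_cohort(25, config, seed=3)
result = analyze_dataset(dataset.events, dataset.rpeaks, subjects=subjects)

for cond in ("execution", "observation"):
    ray = result["phase"]["group_rayleigh"][cond]
    print(f"{cond}: subject-mean Rayleigh z = {ray.z:.2f}, p = {ray.p:.2f}")

per_bin = result["phase"]["per_bin"]["execution"]
flagged = per_bin[per_bin["sig_unc"]]
print("\nexecution bins above/below 0.05 (uncorrected p < .05):")
print(
    flagged[["bin_center_deg", "mean_prop", "t", "p_unc", "p_bonf"]]
    .round(3)
    .to_string(index=False)
)
# With kappa = 0.5 the preference is weak: single-subject phases stay far
# from concentrated (the Rayleigh test on subject means often stays
# non-significant), while the per-bin test picks up the elevated proportion
# in the bin centered on 81 degrees; such small effects rarely survive the
# 20-bin Bonferroni correction.
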