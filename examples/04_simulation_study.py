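"""Monte-Carlo comparison of the three estimators across pleiotropy regimes.

Three scenarios with known ground truth show why the analysis triangulates
across IVW, MR-Egger and the penalized weighted median: each estimator is
consistent under a different assumption about pleiotropy.
"""

from mrkit import ScenarioConfig, replicate_study

COLS = ["estimator", "bias", "mc_se_bias", "coverage", "rejection_rate"]

print("1) Valid instrument, no causal effect (everything should behave):")
null = ScenarioConfig(seed=1)
print(replicate_study(null, 500, estimators=("ivw", "egger", "pwm"))[COLS]
      .to_string(index=False))
print()

print("2) Directional pleiotropy on every SNP (InSIDE holds), true effect 0:")
directional = ScenarioConfig(seed=2, instrument_betas=(0.05, 0.15),
                             pleiotropy="directional_inside", pleio_sd=0.05)
print(replicate_study(directional, 500, estimators=("ivw", "egger"))[COLS]
      .to_string(index=False))
print()

print("3) 40% of SNPs invalid with large directional pleiotropy, true effect 0.1:")
invalid40 = ScenarioConfig(seed=3, instrument_betas=(0.05, 0.15),
                           true_effect=0.1, pleiotropy="directional_inside",
                           pleio_sd=0.3, invalid_fraction=0.4)
print(replicate_study(invalid40, 500, estimators=("ivw", "pwm"))[COLS]
      .to_string(index=False))
print()
print("Scenario 1: IVW is unbiased with ~95% CI coverage and ~5% false-positive")
print("rate. Scenario 2: directional pleiotropy biases IVW (coverage collapses)")
print("while MR-Egger stays unbiased. Scenario 3: IVW is useless, while the")
print("penalized weighted median lands close to the true 0.1 — it retains a")
print("small positive finite-sample bias under one-sided contamination,")
print("discussed in docs/methods.md.")
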