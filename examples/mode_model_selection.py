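"""Fit the four evolutionary-mode models to simulated trait series.

Draws one series from an unbiased random walk and one from a directional
walk (both with known sampling error), fits all four models by maximum
likelihood, and prints the AICc table. The lowest AICc marks the
best-supported mode; Akaike weights give the probability each model is
best within the candidate set.
"""

from traitwalls import ModeParams, fit_four_models, simulate_mode_series

scenarios = {
    "unbiased random walk (mu = 0, sigma2 = 1)":
        simulate_mode_series("URW", ModeParams(anc=0.0, sigma2_step=1.0),
                             n_samples=80, sizes=20, within_sample_var=0.5, seed=1),
    "directional walk (mu = 0.5, sigma2 = 1)":
        simulate_mode_series("GRW", ModeParams(anc=0.0, mu_step=0.5, sigma2_step=1.0),
                             n_samples=80, sizes=20, within_sample_var=0.5, seed=2),
}

for label, series in scenarios.items():
    print(f"\ngenerating process: {label}")
    print(f"{'model':<14}{'lnL':>10}{'k':>4}{'AICc':>12}{'weight':>9}")
    for fit in fit_four_models(series):
        print(f"{fit.model:<14}{fit.loglik:>10.2f}{fit.k_params:>4}"
              f"{fit.aicc:>12.2f}{fit.akaike_weight:>9.3f}")

print("\nA weight near 1.000 for the generating model shows the AICc "
      "selection recovering the true mode; URW vs GRW can legitimately "
      "stay ambiguous when a driftless walk happens to wander.")
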