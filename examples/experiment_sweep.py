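"""Monte-Carlo sweep of the landscape comparison, with summary plot.

Runs the five-estimator comparison over a grid of sampling fractions
(25 replicates per setting to keep this example quick; the full study
uses 100) at proxy correlation 0.75, prints the tidy per-setting summary,
evaluates the headline ordering flags and writes the two-panel
bias / CI-width figure to experiment_sweep.png.
"""
import biogaps as bg
from biogaps.plotting import plot_bias_ciwidth

cfg = bg.ExperimentConfig(scenario="fig5", n_runs=25, seed=3, sweep="fraction",
                          fractions=(0.15, 0.35, 0.75))
result = bg.run_fig5(cfg)

cols = ["fraction", "method", "mean_bias", "mc_se_bias", "mean_ci_width",
        "coverage"]
print(result.table[cols].round(3).to_string(index=False))

summary, flags = bg.summarize(result)
print("\nheadline orderings at the fixed setting:")
for name, value in flags.items():
    print(f"  {name}: {value}")

path = plot_bias_ciwidth(result, "experiment_sweep.png", sweep="fraction")
print(f"\nwrote {path}; each point is a mean over {cfg.n_runs} replicates — "
      "bias shrinks and intervals tighten as the sampled fraction grows.")
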