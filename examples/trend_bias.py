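"""MNAR gaps bias a species trend; MCAR gaps only add noise.

Simulates a 50-site, 15-year monitoring panel whose site covariate (think
urban cover) drives site-level trends: populations are stable or slightly
increasing at low covariate values and declining at high ones.  Two gap
mechanisms then delete half the site-year records: completely at random,
or preferentially keeping high-covariate (declining) sites.  The mean
trend (year effect of a Poisson GLM with site effects) is compared with
the dense-panel estimate over 50 Monte-Carlo replicates.
"""
import numpy as np

import biogaps as bg

cfg = bg.ExperimentConfig(scenario="fig3", n_runs=50, seed=7)
table = bg.run_fig3(cfg).table.set_index("setting")

print("mean trend bias relative to the dense panel (log-units/year):")
for arm in ("mcar", "mnar"):
    row = table.loc[arm]
    z = row["mean_bias"] / row["mc_se_bias"]
    print(f"  {arm.upper():5s}: {row['mean_bias']:+.4f} "
          f"(MC SE {row['mc_se_bias']:.4f}, z = {z:+.1f})")

print("\nUnder MCAR the masked estimate tracks the dense one; under MNAR "
      "the surviving sites are disproportionately the declining ones, so "
      "the estimated mean trend is biased downward.")
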