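"""Estimate a landscape mean under covariate-driven sampling gaps.

Builds one 400-cell landscape whose habitat-quality covariate raises both
species abundance and the chance a cell gets surveyed, masks it to a 35%
sample, and compares the five estimators of the landscape mean against the
realized truth.  Positive bias means the estimator mistakes the
preferential coverage of good habitat for a genuinely more abundant species.
"""
import biogaps as bg

land = bg.attach_proxy(bg.make_landscape(400, 20, seed=1), rho=0.75, seed=2)
dense = bg.simulate_counts(land, alpha=1.0, beta=0.8, seed=3)
truth = dense.table["count"].mean()
print(f"realized landscape mean abundance (truth): {truth:.3f}")
print(f"realized proxy correlation: {land.realized_proxy_corr:.3f}")

x = dense.table.set_index("cell_id")["x_true"]
design = bg.inclusion_probs(x, "logistic", {"slope": 2.0}, target_fraction=0.35)
mask = bg.draw_mask(design, dimension="spatial", seed=4)
observed = bg.apply_mask(dense, mask)
print(f"cells surveyed: {mask.n_included}/400 "
      f"(realized fraction {mask.realized_fraction:.3f})\n")

proxy_level = observed.table["x_proxy_level"].to_numpy()
pop_sizes = land.table["x_proxy_level"].value_counts().sort_index()
pi_proxy = bg.inclusion_probs(land.table.set_index("cell_id")["x_proxy"],
                              "logistic", {"slope": 2.0}, 0.35).pi

estimates = [
    bg.estimate_naive(observed),
    bg.estimate_naive(bg.subsample_balanced(observed, proxy_level, k=1, seed=5),
                      method="subsampled"),
    bg.estimate_ipw(observed, pi_proxy),
    bg.estimate_poststrat(observed, proxy_level, pop_sizes),
    bg.estimate_impute_bayes(observed, land, seed=6),
]
print(f"{'method':14s} {'point':>7s} {'bias':>7s} {'95% interval':>16s}")
for e in estimates:
    print(f"{e.method:14s} {e.point:7.3f} {e.point - truth:+7.3f} "
          f"[{e.ci_low:6.3f}, {e.ci_high:6.3f}]")
print("\nThe naive mean inherits the full sampling bias; weighting by the "
      "inverse of the (proxy-evaluated) inclusion probability removes most "
      "of it, at the price of a wider interval.")
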