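"""Monte-Carlo validation: does weighting recover the known truth?

Compares three estimators on strongly confounded cohorts — the naive
regression, a covariate-adjusted regression (which wrongly conditions on
the mediator x1), and quantile-binned IPTW — then sweeps the bin count K.
Replicate counts here are small for speed; raise them for tighter numbers.
"""

import quantiptw as q

truth = q.truth_strong_confounding()
res = q.run_scenario(truth, n=1000, k=8, replicates=20, seed=7)
print(f"truth: delta1 = {res.truth['delta1']:.4f}, delta2 = {res.truth['delta2']:.4f}")
cols = ["estimator", "coefficient", "bias", "empirical_se", "rmse", "coverage"]
print(res.summary[cols].round(4).to_string(index=False))
print("\nnaive is biased by family background and the child's mid-stream "
      "language; IPTW removes most of it.  'adjusted' fixes delta2 but "
      "distorts delta1 by conditioning on a mediator.\n")

print("bin-count sweep (same cohorts, only K varies):")
for r in q.quantile_sweep(truth, n=1000, k_list=[2, 4, 8], replicates=10, seed=7):
    row = r.summary.set_index(["estimator", "coefficient"]).loc[("iptw", "delta2")]
    print(f"  K = {r.k}: IPTW delta2 bias {row['bias']:+.4f}")
print("finer bins leave less within-bin confounding, at the cost of "
      "noisier bin-membership models.")
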