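#!/usr/bin/env python
"""Fit the propensity model and compute IPT weights with balance checks.

Logistic propensity model on the baseline covariates; weights 1/PS and
1/(1-PS) normalized by the grand mean, so the weighted cohort sizes sum
to the unweighted total.  Writes weights and standardized-difference
balance tables before and after weighting.
"""

import argparse

import pandas as pd

from claimsce.cohort import ps_design
from claimsce.iptw import balance_table, compute_weights, fit_propensity

parser = argparse.ArgumentParser()
parser.add_argument("--results", default="results")
args = parser.parse_args()

table = pd.read_csv(f"{args.results}/cohort.csv", dtype={"patient_id": str})
cov = pd.read_csv(f"{args.results}/covariates.csv", dtype={"patient_id": str})
treated = (table["cohort"] == "PP1M").to_numpy()

design = ps_design(cov)
fit = fit_propensity(design.to_numpy(), treated, columns=list(design.columns))
weights = compute_weights(fit.ps, treated)
pre = balance_table(design, treated)
post = balance_table(design, treated, weights.normalized)

pd.DataFrame({"patient_id": table["patient_id"], "ps": fit.ps, "weight": weights.normalized}).to_csv(
    f"{args.results}/weights.csv", index=False
)
pre.to_csv(f"{args.results}/balance_unweighted.csv", index=False)
post.to_csv(f"{args.results}/balance_weighted.csv", index=False)

print(f"propensity fit: {fit.n_iter} iterations, |grad| = {fit.grad_norm:.2e}")
print(f"weighted N = {weights.normalized.sum():.9f} (unweighted {len(table)})")
print(f"covariates with |std diff| > 10% before weighting: {(pre['std_diff_pct'] > 10).sum()}")
print(f"max |std diff| after weighting: {post['std_diff_pct'].max():.2f}% "
      f"({'balanced' if (post['std_diff_pct'] <= 10).all() else 'NOT balanced'})")
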