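#!/usr/bin/env python
"""Diagnose the visit-level PGA missingness mechanism.

Logistic GEE (exchangeable working correlation, robust errors, patients as
clusters) for the probability that a visit's PGA is missing, with sex, age
at diagnosis, time since diagnosis, baseline PGA and centre as candidate
predictors.  In the generating model only baseline PGA and centre matter.
"""

from pathlib import Path

import pandas as pd

from trajmix import gee
from trajmix.cohort import read_cohort

OUT = Path("results/analysis")
cohort = read_cohort(OUT / "baseline.csv", OUT / "visits.csv")

res = gee.fit_gee_missingness(cohort)
table = pd.DataFrame({
    "coef": res.params, "robust_se": res.robust_se,
    "naive_se": res.naive_se, "z": res.zvalues, "p": res.pvalues,
})
table.to_csv(OUT / "gee_missingness.csv")
print(table.round(4))
print(f"\nexchangeable correlation alpha = {res.alpha:.4f}, "
      f"{res.n_clusters} patient clusters")
sig = table[(table["p"] < 0.05) & (table.index != "const")].index.tolist()
print(f"predictors with p<0.05: {sig}")
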