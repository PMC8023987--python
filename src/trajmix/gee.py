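"""Visit-level missingness diagnostic: logistic GEE with robust errors.

Response: indicator that the visit's PGA is missing.  Clusters: patients (the
same patient can miss the outcome at several visits).  Working correlation:
exchangeable, with the sandwich (robust) covariance reported alongside the
naive one.  Fitted through statsmodels' GEE machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort

DEFAULT_PREDICTORS = ("sex", "age_at_diagnosis", "t", "pga0", "centre")


@dataclass
class GEEResult:
    params: pd.Series
    robust_se: pd.Series
    naive_se: pd.Series
    alpha: float                 # exchangeable correlation estimate
    n_clusters: int
    zvalues: pd.Series
    pvalues: pd.Series
    robust_cov: pd.DataFrame
    converged: bool


def build_missingness_frame(cohort: Cohort,
                            predictors=DEFAULT_PREDICTORS) -> pd.DataFrame:
    """One row per visit: missing-PGA indicator plus visit/baseline predictors.

    Visits of patients with a missing value in any requested baseline
    predictor are dropped (complete-case diagnostic).
    """
    base = cohort.baseline.set_index("patient_id")
    df = cohort.visits[["patient_id", "t", "pga"]].copy()
    df["missing"] = df["pga"].isna().astype(int)
    for name in predictors:
        if name == "t":
            continue
        if name == "sex":
            df["male"] = (df["patient_id"].map(base["sex"]) == "M").astype(float)
        elif name == "centre":
            df["centre_a"] = (df["patient_id"].map(base["centre"]) == "A"
                              ).astype(float)
        else:
            df[name] = df["patient_id"].map(base[name]).astype(float)
    if "t" not in predictors:
        df = df.drop(columns=["t"])
    df = df.drop(columns=["pga"]).dropna()
    return df


def fit_gee_missingness(cohort: Cohort, predictors=DEFAULT_PREDICTORS,
                        correlation: str = "exchangeable") -> GEEResult:
    """Fit the logistic GEE for P(PGA missing) with patient clusters."""
    df = build_missingness_frame(cohort, predictors)
    cols = [c for c in df.columns if c not in ("patient_id", "missing")]
    X = sm.add_constant(df[cols])
    if correlation == "exchangeable":
        cov_struct = sm.cov_struct.Exchangeable()
    elif correlation == "independence":
        cov_struct = sm.cov_struct.Independence()
    else:
        raise ValueError(f"unknown working correlation {correlation!r}")
    model = sm.GEE(df["missing"], X, groups=df["patient_id"],
                   family=sm.families.Binomial(), cov_struct=cov_struct)
    res = model.fit(maxiter=200, ctol=1e-8)
    naive = np.asarray(res.cov_naive)
    alpha = float(cov_struct.dep_params) if correlation == "exchangeable" else 0.0
    return GEEResult(
        params=res.params,
        robust_se=res.bse,
        naive_se=pd.Series(np.sqrt(np.diag(naive)), index=res.params.index),
        alpha=alpha,
        n_clusters=df["patient_id"].nunique(),
        zvalues=res.tvalues,
        pvalues=res.pvalues,
        robust_cov=pd.DataFrame(np.asarray(res.cov_params()),
                                index=res.params.index,
                                columns=res.params.index),
        converged=bool(getattr(res, "converged", True)),
    )
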