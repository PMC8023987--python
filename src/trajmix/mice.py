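"""Multiple imputation of missing baseline features by chained equations.

Produces m completed copies of the baseline table for the predictive stage.
Imputation runs through statsmodels' chained-equations machinery with
predictive mean matching (PMM, k donors): every imputed value is an observed
donor value, so types and ranges are preserved by construction — numeric
scores stay in range and binary features stay in {0, 1}.

The trajectory-class outcome is NOT used as an imputation predictor by
default (conservative; a flag exposes the alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.imputation.mice import MICEData

#: baseline columns that may legitimately contain missing values
IMPUTABLE_COLUMNS = [
    "pga0", "cmas0", "das0",
    "arthritis", "abnormal_respiration", "calcinosis",
    "lipodystrophy", "ulceration",
]
#: fully observed numeric/binary helper predictors used by every equation
AUXILIARY_COLUMNS = ["age_at_diagnosis", "time_to_first_visit"]


@dataclass
class ImputationSet:
    tables: list[pd.DataFrame]       # m completed baseline tables
    method_map: dict[str, str]
    n_iter: int
    seed: int
    missing_mask: pd.DataFrame       # True where the input was missing

    @property
    def m(self) -> int:
        return len(self.tables)


def _numeric_frame(baseline: pd.DataFrame, extra_predictors) -> pd.DataFrame:
    df = pd.DataFrame(index=baseline.index)
    for col in IMPUTABLE_COLUMNS + AUXILIARY_COLUMNS:
        df[col] = baseline[col].astype(float)
    df["male"] = (baseline["sex"] == "M").astype(float)
    df["centre_a"] = (baseline["centre"] == "A").astype(float)
    for name, vals in (extra_predictors or {}).items():
        df[name] = np.asarray(vals, dtype=float)
    return df


def impute(baseline: pd.DataFrame, m: int = 10, n_iter: int = 10,
           seed: int = 0, k_pmm: int = 5,
           extra_predictors: dict | None = None) -> ImputationSet:
    """Chained-equations imputation: m completed baseline tables.

    Each of the m datasets runs its own independently seeded chain for
    ``n_iter`` sweeps.  Fully missing columns are rejected.  Demographics
    (sex, centre, age, time to first visit) enter every imputation equation
    as fully observed predictors; ``extra_predictors`` can add more (e.g.
    class membership, behind the non-default flag in the pipeline).
    """
    work = _numeric_frame(baseline, extra_predictors)
    mask = work[IMPUTABLE_COLUMNS].isna()
    for col in IMPUTABLE_COLUMNS:
        if work[col].isna().all():
            raise ValueError(f"column {col!r} is entirely missing")
    if not work.drop(columns=IMPUTABLE_COLUMNS).notna().all().all():
        raise ValueError("auxiliary predictors must be fully observed")

    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(m)
    tables = []
    for j in range(m):
        # statsmodels' chained-equations sampler draws from the global
        # numpy RandomState; give each dataset its own stream
        np.random.seed(int(streams[j].generate_state(1)[0] % (2 ** 31)))
        imp = MICEData(work.copy(), k_pmm=k_pmm)
        if mask.to_numpy().any():
            imp.update_all(n_iter)
        completed = baseline.copy()
        for col in IMPUTABLE_COLUMNS:
            completed[col] = imp.data[col].to_numpy()
        tables.append(completed)
    method = {col: f"pmm(k={k_pmm})" for col in IMPUTABLE_COLUMNS}
    return ImputationSet(tables=tables, method_map=method, n_iter=n_iter,
                         seed=seed, missing_mask=mask)
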