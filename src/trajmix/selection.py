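"""Model selection: single-class structure search, then 1..G_max classes.

The single-class search picks the outcome transform and time polynomial by
BIC; that structure is then refitted with increasing numbers of classes, and
the preferred class count minimizes BIC, with the entropy-maximal count
reported alongside (a conflict between the two criteria is flagged, not
silently resolved).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import Cohort
from .gmm import GMMFit, GMMSpec, fit_gmm


@dataclass
class SelectionResult:
    table: pd.DataFrame
    fits: dict[int, GMMFit]         # keyed by G; failed fits absent
    base_spec: GMMSpec              # winning single-class structure
    structure_table: pd.DataFrame | None = None


def search_structure(cohort: Cohort, base_spec: GMMSpec,
                     transforms=("identity", "sqrt"), degrees=(1, 2, 3),
                     n_starts: int = 1, seed: int = 0,
                     max_iter: int = 300) -> tuple[GMMSpec, pd.DataFrame]:
    """Fit G=1 models over (transform, degree) candidates; lowest BIC wins."""
    rows = []
    best = None
    for tr in transforms:
        for d in degrees:
            spec = replace(base_spec, n_classes=1, transform=tr, time_degree=d)
            try:
                fit = fit_gmm(cohort, spec, n_starts=n_starts, seed=seed,
                              max_iter=max_iter)
            except (ValueError, FloatingPointError) as exc:
                rows.append({"transform": tr, "degree": d, "loglik": np.nan,
                             "bic": np.nan, "error": str(exc)})
                continue
            rows.append({"transform": tr, "degree": d, "loglik": fit.loglik,
                         "bic": fit.bic, "error": ""})
            if best is None or fit.bic < best[0]:
                best = (fit.bic, spec)
    table = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError("no single-class structure could be fitted")
    return replace(best[1], n_classes=base_spec.n_classes), table


def fit_range(cohort: Cohort, base_spec: GMMSpec, G_max: int = 6,
              n_starts: int = 4, seed: int = 0, max_iter: int = 300,
              search: bool = False) -> SelectionResult:
    """Fit 1..G_max-class models with the (optionally searched) structure.

    A failed fit marks its row rather than aborting the table.
    """
    if G_max < 2:
        raise ValueError("G_max must be >= 2")
    structure_table = None
    spec = base_spec
    if search:
        spec, structure_table = search_structure(
            cohort, base_spec, n_starts=max(1, n_starts // 2), seed=seed,
            max_iter=max_iter)

    rows = []
    fits: dict[int, GMMFit] = {}
    for G in range(1, G_max + 1):
        gspec = replace(spec, n_classes=G)
        row = {"G": G, "loglik": np.nan, "k": gspec.n_params(), "bic": np.nan,
               "entropy": np.nan, "class_probs": None,
               "mean_posterior_by_class": None, "converged": False,
               "error": ""}
        try:
            fit = fit_gmm(cohort, gspec, n_starts=n_starts if G > 1 else 1,
                          seed=seed, max_iter=max_iter)
        except (ValueError, FloatingPointError) as exc:
            row["error"] = str(exc)
            rows.append(row)
            continue
        fits[G] = fit
        row.update(
            loglik=fit.loglik, bic=fit.bic,
            entropy=fit.entropy if fit.entropy is not None else np.nan,
            class_probs=tuple(np.round(fit.params.class_probs, 4)),
            mean_posterior_by_class=tuple(
                np.round(fit.mean_posterior_by_class, 4)),
            converged=fit.convergence["converged"],
        )
        rows.append(row)
    return SelectionResult(table=pd.DataFrame(rows), fits=fits,
                           base_spec=spec, structure_table=structure_table)


def select_model(table: pd.DataFrame) -> dict:
    """Pick the class count minimizing BIC among converged rows.

    When the entropy-maximal count disagrees, BIC wins and the conflict is
    recorded in the returned summary.
    """
    ok = table[table["converged"] & np.isfinite(table["bic"])]
    if ok.empty:
        raise ValueError("no converged fits to select from")
    g_bic = int(ok.loc[ok["bic"].idxmin(), "G"])
    multi = ok[ok["G"] >= 2]
    g_ent = int(multi.loc[multi["entropy"].idxmax(), "G"]) \
        if not multi.empty and multi["entropy"].notna().any() else None
    return {
        "selected_G": g_bic,
        "bic_G": g_bic,
        "entropy_G": g_ent,
        "criteria_conflict": g_ent is not None and g_ent != g_bic,
    }
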