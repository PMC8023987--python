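"""End-to-end analysis pipeline and reporting helpers.

Stage order mirrors the study design: truncate follow-up, diagnose the
missingness mechanism (GEE), fit and select growth mixture models for the
global (PGA) and skin (DAS) outcomes, cross-tabulate the modal classes,
impute baseline features, and run the posterior-weighted lasso for the
severe PGA class.  Each stage writes flat CSV/JSON artifacts into the run
directory and registers itself in a manifest, so every reported number is
traceable to an artifact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import gee, lasso, mice, selection, simulate
from .cohort import Cohort, read_cohort, truncate_followup, write_cohort
from .gmm import GMMFit, GMMSpec


@dataclass
class PipelineConfig:
    """Configuration of a full run; defaults follow the study's analysis."""

    outdir: str = "run"
    seed: int = 0
    baseline_path: str | None = None      # load a cohort ...
    visits_path: str | None = None
    simulate: bool = True                 # ... or simulate one
    n_patients: int = 519
    horizon: float = 10.0
    G_max: int = 6
    n_starts: int = 4
    max_iter: int = 300
    m_imputations: int = 10
    mice_iter: int = 10
    cv_folds: int = 10
    loss: str = "auc"
    search_structure: bool = False
    subsets: tuple[str, ...] = ()
    pga_spec: GMMSpec = field(default_factory=lambda: GMMSpec(
        n_classes=2, time_degree=3, transform="sqrt",
        covariates=("centre",), outcome="pga"))
    das_spec: GMMSpec = field(default_factory=lambda: GMMSpec(
        n_classes=3, time_degree=3, transform="sqrt",
        covariates=(), outcome="das"))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("pga_spec", "das_spec"):
            if key in raw:
                raw[key] = GMMSpec(**raw[key])
        if "subsets" in raw:
            raw["subsets"] = tuple(raw["subsets"])
        return cls(**raw)


def cross_tabulate(fit_a: GMMFit, fit_b: GMMFit) -> dict:
    """Modal-class cross-tabulation of two fits on their shared patients.

    Returns counts plus row percentages (within classes of fit A) and column
    percentages (within classes of fit B); patients classified by only one
    model are excluded with a recorded count.
    """
    a = fit_a.modal_class
    b = fit_b.modal_class
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("the two fits share no patients")
    counts = pd.crosstab(a.loc[shared], b.loc[shared])
    counts = counts.reindex(
        index=range(1, fit_a.spec.n_classes + 1),
        columns=range(1, fit_b.spec.n_classes + 1), fill_value=0)
    return {
        "counts": counts,
        "row_pct": crosstab_percentages(counts.to_numpy(), axis=1),
        "col_pct": crosstab_percentages(counts.to_numpy(), axis=0),
        "n_excluded": int(len(a.index.union(b.index)) - len(shared)),
    }


def crosstab_percentages(counts, axis: int) -> np.ndarray:
    """Percentages of a contingency table along rows (axis=1) or columns
    (axis=0), to one decimal's worth of precision when printed."""
    counts = np.asarray(counts, float)
    sums = counts.sum(axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * counts / sums
    return np.where(np.isfinite(pct), pct, np.nan)


def sensitivity_subsets(cohort: Cohort, toggles) -> dict[str, Cohort]:
    """Named sub-cohorts for sensitivity analyses.

    ``females`` / ``males``; ``inception`` (first visit within one month of
    diagnosis); ``no_late_entry`` (drop entry >= 5 years after diagnosis);
    ``no_late_entry_min3`` (additionally drop patients with < 3 visits; a
    patient with exactly 3 visits is retained).  Empty subsets are skipped.
    """
    out: dict[str, Cohort] = {}
    base = cohort.baseline

    def restrict(keep_ids) -> Cohort | None:
        keep_ids = set(keep_ids)
        b = base[base["patient_id"].isin(keep_ids)].reset_index(drop=True)
        v = cohort.visits[cohort.visits["patient_id"].isin(keep_ids)
                          ].reset_index(drop=True)
        if b.empty:
            return None
        return Cohort(baseline=b, visits=v)

    nvisits = cohort.visits.groupby("patient_id").size()
    for name in toggles:
        if name == "females":
            sub = restrict(base.loc[base["sex"] == "F", "patient_id"])
        elif name == "males":
            sub = restrict(base.loc[base["sex"] == "M", "patient_id"])
        elif name == "inception":
            sub = restrict(base.loc[base["time_to_first_visit"] <= 1.0 / 12.0,
                                    "patient_id"])
        elif name == "no_late_entry":
            sub = restrict(base.loc[base["time_to_first_visit"] < 5.0,
                                    "patient_id"])
        elif name == "no_late_entry_min3":
            ids = base.loc[base["time_to_first_visit"] < 5.0, "patient_id"]
            sub = restrict([p for p in ids if nvisits.get(p, 0) >= 3])
        else:
            raise ValueError(f"unknown subset toggle {name!r}")
        if sub is None:
            import warnings
            warnings.warn(f"subset {name!r} is empty; skipped")
        else:
            out[name] = sub
    return out


def characterize_classes(cohort: Cohort, fit: GMMFit) -> pd.DataFrame:
    """Per-modal-class summary: n, %, median (Q1-Q3) of continuous baseline
    variables, count (%) of binary/categorical ones."""
    base = cohort.baseline.set_index("patient_id")
    modal = fit.modal_class
    base = base.loc[base.index.intersection(modal.index)]
    modal = modal.loc[base.index]
    rows = []
    n_total = len(modal)
    cont = ["age_at_diagnosis", "time_to_first_visit", "pga0", "cmas0", "das0"]
    cats = ["sex", "ethnicity", "diagnosis", "centre"] + [
        "arthritis", "abnormal_respiration", "calcinosis", "lipodystrophy",
        "ulceration"]
    for g in range(1, fit.spec.n_classes + 1):
        sub = base[modal == g]
        row = {"class": g, "n": len(sub),
               "pct": 100.0 * len(sub) / n_total if n_total else np.nan}
        for c in cont:
            q1, q2, q3 = sub[c].quantile([0.25, 0.5, 0.75])
            row[f"{c}_median"] = q2
            row[f"{c}_q1"], row[f"{c}_q3"] = q1, q3
        for c in cats:
            if c in ("sex", "centre", "ethnicity", "diagnosis"):
                top = sub[c].mode()
                row[f"{c}_top"] = top.iloc[0] if len(top) else None
            else:
                row[f"{c}_n"] = float(sub[c].sum())
                denom = sub[c].notna().sum()
                row[f"{c}_pct"] = 100.0 * sub[c].mean() if denom else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration

STAGES = ["load", "truncate", "missingness", "gmm_pga", "gmm_das",
          "crosstab", "impute", "lasso"]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; artifacts and a manifest land in ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def done(stage, **artifacts):
        manifest["stages"][stage] = {"status": "complete", **artifacts}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    try:
        # load -------------------------------------------------------------
        if config.simulate:
            pga_sim = simulate.default_study_spec(
                n_patients=config.n_patients, seed=config.seed)
            das_sim = simulate.default_das_spec(
                n_patients=config.n_patients, seed=config.seed)
            cohort, truth = simulate.simulate_cohort(pga_sim,
                                                     das_spec=das_sim)
            truth.labels.to_csv(out / "sim_truth.csv", index=False)
        else:
            cohort = read_cohort(config.baseline_path, config.visits_path)
        write_cohort(cohort, out / "baseline.csv", out / "visits.csv")
        done("load", baseline="baseline.csv", visits="visits.csv",
             n_patients=cohort.n_patients, n_visits=cohort.n_visits)

        # truncate ----------------------------------------------------------
        cohort = truncate_followup(cohort, config.horizon)
        write_cohort(cohort, out / "baseline_trunc.csv",
                     out / "visits_trunc.csv")
        done("truncate", horizon=config.horizon, n_visits=cohort.n_visits)

        # missingness diagnostic --------------------------------------------
        geer = gee.fit_gee_missingness(cohort)
        pd.DataFrame({
            "coef": geer.params, "robust_se": geer.robust_se,
            "naive_se": geer.naive_se, "z": geer.zvalues, "p": geer.pvalues,
        }).to_csv(out / "gee_missingness.csv")
        done("missingness", table="gee_missingness.csv",
             alpha=geer.alpha, n_clusters=geer.n_clusters)

        # GMMs --------------------------------------------------------------
        fits = {}
        selections = {}
        for label, gspec in (("pga", config.pga_spec),
                             ("das", config.das_spec)):
            sel = selection.fit_range(
                cohort, gspec, G_max=config.G_max, n_starts=config.n_starts,
                seed=config.seed, max_iter=config.max_iter,
                search=config.search_structure)
            choice = select_or_none(sel.table)
            G = choice["selected_G"] if choice else gspec.n_classes
            fit = sel.fits.get(G) or sel.fits[max(sel.fits)]
            fits[label] = fit
            selections[label] = sel
            sel.table.to_csv(out / f"selection_{label}.csv", index=False)
            fit.to_json(out / f"gmm_{label}.json",
                        posterior_path=out / f"posterior_{label}.csv")
            characterize_classes(cohort, fit).to_csv(
                out / f"classes_{label}.csv", index=False)
            done(f"gmm_{label}", selected_G=G,
                 table=f"selection_{label}.csv", fit=f"gmm_{label}.json",
                 conflict=bool(choice and choice["criteria_conflict"]))

        # cross-tabulation ---------------------------------------------------
        ct = cross_tabulate(fits["pga"], fits["das"])
        ct["counts"].to_csv(out / "crosstab_counts.csv")
        pd.DataFrame(ct["row_pct"]).to_csv(out / "crosstab_row_pct.csv")
        pd.DataFrame(ct["col_pct"]).to_csv(out / "crosstab_col_pct.csv")
        done("crosstab", counts="crosstab_counts.csv",
             n_excluded=ct["n_excluded"])

        # imputation ---------------------------------------------------------
        imps = mice.impute(cohort.baseline, m=config.m_imputations,
                           n_iter=config.mice_iter, seed=config.seed)
        for j, tab in enumerate(imps.tables):
            tab.to_csv(out / f"imputed_{j:02d}.csv", index=False)
        done("impute", m=imps.m, n_iter=imps.n_iter)

        # weighted lasso ------------------------------------------------------
        # the predictive stage is defined on the 2-class global-activity
        # model; fall back to the fitted G=2 model if selection preferred
        # another class count
        pga_fit = fits["pga"] if fits["pga"].spec.n_classes == 2 \
            else selections["pga"].fits[2]
        weighted = lasso.build_weighted_response(pga_fit)
        results = []
        for j, tab in enumerate(imps.tables):
            task = lasso.make_task(lasso.build_design(tab), weighted)
            results.append(lasso.fit_lasso_cv(
                task, n_folds=config.cv_folds, loss=config.loss,
                seed=config.seed + j))
        pooled = lasso.pool_over_imputations(results)
        pd.DataFrame({
            "coef": pooled.pooled_coef, "odds_ratio": pooled.pooled_or,
        }).to_csv(out / "lasso_pooled.csv")
        pooled.retention_counts.to_csv(out / "lasso_retention.csv")
        done("lasso", retained=pooled.retained, pooled="lasso_pooled.csv")

        # sensitivity subsets -------------------------------------------------
        if config.subsets:
            subs = sensitivity_subsets(cohort, config.subsets)
            info = {}
            for name, sub in subs.items():
                write_cohort(sub, out / f"subset_{name}_baseline.csv",
                             out / f"subset_{name}_visits.csv")
                info[name] = sub.n_patients
            done("subsets", **info)
    except Exception as exc:
        stage = next((s for s in STAGES if s not in manifest["stages"]), "?")
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out


def select_or_none(table):
    try:
        return selection.select_model(table)
    except ValueError:
        return None
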