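"""End-to-end orchestration of the audit with reproducible run artifacts.

One master seed governs every stage through name-hashed stage seeds.  A run
produces, for each balancing regime (none, or balancing on one SES measure)
and each model family: per-measure subgroup metric tables, baseline-contrast
flag tables, and a pooled-sex relative-BER-difference matrix — plus cohort
descriptives (case/control counts, SES distributions, visit-count and
missed-years means, the SES concordance matrix and a per-category prevalence
ranking by case status).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import audit as audit_mod
from . import io as io_mod
from .cohort import build_cohort
from .config import (
    MEASURES,
    MitigationConfig,
    RunConfig,
    SplitConfig,
    config_hash,
    stage_seed,
)
from .features import _windowed_visits, build_feature_matrix
from .mitigation import balance_protected
from .models import default_specs, fast_specs, predict_labels, split_data, tune_and_fit
from .synthetic import compute_concordance, generate_population, missed_years_summary


def category_prevalence(
    cohort: pd.DataFrame,
    visits: pd.DataFrame,
    n_categories: int,
    timeline=None,
    mapping: dict | None = None,
) -> pd.DataFrame:
    """Fraction of eligible cases/controls with at least one observation-
    window visit carrying each category, sorted by the case fraction."""
    from .config import TimelineConfig

    timeline = timeline or TimelineConfig()
    elig = cohort.loc[cohort["eligible"]].reset_index(drop=True)
    v = _windowed_visits(elig, visits, timeline.observation_years)
    tokens = v["categories"].fillna("").astype(str).str.split(";")
    pairs = v[["patient_id"]].assign(token=tokens).explode("token")
    pairs = pairs[pairs["token"].astype(str).str.len() > 0]
    if mapping is not None:
        pairs["cat"] = pairs["token"].map(mapping)
        pairs = pairs.dropna(subset=["cat"])
        pairs["cat"] = pairs["cat"].astype(int)
    else:
        pairs["cat"] = pairs["token"].astype(int)
    pairs = pairs.drop_duplicates(["patient_id", "cat"])
    label = elig.set_index("patient_id")["label"]
    pairs["label"] = pairs["patient_id"].map(label)
    n_case = int((elig["label"] == 1).sum())
    n_control = int((elig["label"] == 0).sum())
    rows = []
    for c in range(1, n_categories + 1):
        sub = pairs[pairs["cat"] == c]
        rows.append(
            {
                "category": c,
                "case": (sub["label"] == 1).sum() / n_case if n_case else np.nan,
                "control": (sub["label"] == 0).sum() / n_control if n_control else np.nan,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("case", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def _descriptives(cohort, visits, timeline, n_categories) -> dict:
    elig = cohort.loc[cohort["eligible"]].reset_index(drop=True)
    v = _windowed_visits(elig, visits, timeline.observation_years)
    counts = v.groupby("patient_id").size()
    per_member = elig["patient_id"].map(counts).fillna(0)
    visit_means = per_member.groupby(elig["label"].to_numpy()).mean()
    missed = {
        m: missed_years_summary(elig, visits, timeline, measure=m).to_dict()
        for m in MEASURES
    }
    ses_dist = {
        m: elig.groupby([f"ses_{m}", "label"]).size().unstack(fill_value=0).to_dict()
        for m in MEASURES
    }
    return {
        "n_eligible": int(len(elig)),
        "n_cases": int((elig["label"] == 1).sum()),
        "n_controls": int((elig["label"] == 0).sum()),
        "visit_count_mean": {int(k): float(val) for k, val in visit_means.items()},
        "missed_years_mean": missed,
        "ses_distribution": {m: {str(k): val for k, val in d.items()}
                             for m, d in ses_dist.items()},
        "prevalence_ranking": category_prevalence(
            cohort, visits, n_categories, timeline
        ).to_dict(orient="records"),
    }


def run_audit(cfg: RunConfig, write: bool = False) -> dict:
    """Execute the full audit; returns the report bundle (optionally
    persisted under ``cfg.output_dir``)."""
    log: list[dict] = []

    def stage(name, **info):
        log.append({"stage": name, **info})

    # --- input tables -----------------------------------------------------
    if cfg.patient_table is None:
        pop = dataclasses.replace(
            cfg.population, seed=stage_seed(cfg.master_seed, "simulate")
        )
        patients, visits = generate_population(pop)
        mapping = None
    else:
        patients = io_mod.read_patients(cfg.patient_table)
        visits = io_mod.read_visits(cfg.visit_table)
        mapping = (
            io_mod.read_mapping(cfg.mapping_table) if cfg.mapping_table else None
        )
    stage("input", n_patients=len(patients), n_visits=len(visits))

    # --- cohort -----------------------------------------------------------
    cohort, ledger = build_cohort(
        patients, visits, cfg.timeline, cfg.dichotomy,
        seed=stage_seed(cfg.master_seed, "cohort"),
    )
    stage("cohort", ledger=ledger, n_eligible=int(cohort["eligible"].sum()))

    # --- features ---------------------------------------------------------
    fm = build_feature_matrix(
        cohort, visits, cfg.population.n_categories, cfg.timeline, mapping
    )
    stage("featurize", rows=len(fm.X), unmapped=fm.n_unmapped_codes)

    split_cfg = SplitConfig(
        train_fraction=cfg.split.train_fraction,
        cv_folds=cfg.split.cv_folds,
        seed=stage_seed(cfg.master_seed, "split"),
    )
    X_tr, X_te, y_tr, y_te = split_data(fm.X, fm.labels.to_numpy(), split_cfg)
    stage("split", n_train=len(X_tr), n_test=len(X_te))

    meta = cohort.loc[cohort["eligible"],
                      ["patient_id", "sex"] + [f"ses_{m}" for m in MEASURES]]
    meta = meta.set_index("patient_id")
    specs = fast_specs() if cfg.grid_preset == "fast" else default_specs()

    regimes = ["none"] + list(cfg.balance_measures)
    predictions: dict[str, pd.DataFrame] = {}
    run_meta: dict[str, dict] = {}
    for regime in regimes:
        if regime == "none":
            Xb, yb = X_tr, y_tr
        else:
            levels = meta.loc[X_tr.index, f"ses_{regime}"].to_numpy()
            mit = MitigationConfig(
                balance_measure=regime,
                seed=42,
                nominal_features=fm.manifest["nominal_columns"],
            )
            balanced = balance_protected(X_tr, y_tr, levels, mit)
            Xb, yb = balanced.X, balanced.y
            stage("mitigate", regime=regime, n_train=len(Xb),
                  n_synthetic=int(balanced.synthetic.sum()))
        for family in cfg.model_families:
            model_cfg = SplitConfig(
                train_fraction=cfg.split.train_fraction,
                cv_folds=cfg.split.cv_folds,
                seed=stage_seed(cfg.master_seed, f"model:{family}"),
            )
            model = tune_and_fit(
                Xb, yb, specs[family], model_cfg,
                continuous_columns=fm.manifest["continuous_columns"],
            )
            y_hat = predict_labels(model, X_te)
            pred = pd.DataFrame(
                {
                    "patient_id": X_te.index.to_numpy(),
                    "y_true": y_te,
                    "y_pred": y_hat,
                    "model_family": family,
                    "regime": regime,
                }
            )
            pred = pred.join(meta, on="patient_id")
            predictions[f"{regime}|{family}"] = pred
            run_meta[f"{regime}|{family}"] = {
                "best_params": {k: str(v) for k, v in model.best_params_.items()}
            }
            stage("train", regime=regime, family=family,
                  best_params=run_meta[f"{regime}|{family}"]["best_params"])

    # --- audit ------------------------------------------------------------
    audits: dict[str, dict] = {}
    rel_rows = []
    for regime in regimes:
        for family in cfg.model_families:
            key = f"{regime}|{family}"
            audits[key] = audit_mod.audit_predictions(
                predictions[key],
                list(cfg.evaluation_measures),
                B=cfg.bootstrap_samples,
                seed=stage_seed(cfg.master_seed, f"audit:{key}"),
            )
        row = {"regime": regime}
        for measure in cfg.evaluation_measures:
            for family in cfg.model_families:
                rel = audits[f"{regime}|{family}"]["measures"][measure][
                    "relative_ber_difference"
                ]
                row[f"{measure}:{family}"] = rel
        rel_rows.append(row)
    rel_table = pd.DataFrame(rel_rows).set_index("regime")
    improved = (rel_table.abs() < rel_table.abs().loc["none"]).drop(index="none",
                                                                    errors="ignore")
    stage("audit", n_prediction_sets=len(predictions))

    bundle = {
        "master_seed": cfg.master_seed,
        "config_hash": config_hash(cfg),
        "exclusion_ledger": ledger,
        "descriptives": _descriptives(
            cohort, visits, cfg.timeline, cfg.population.n_categories
        ),
        "concordance": _concordance_matrix(patients, cfg),
        "cohort": cohort,
        "predictions": predictions,
        "run_meta": run_meta,
        "audits": audits,
        "relative_differences": rel_table,
        "improved_vs_baseline": improved,
        "log": log,
    }
    if write:
        write_bundle(bundle, cfg.output_dir)
    return bundle


def _concordance_matrix(patients: pd.DataFrame, cfg: RunConfig) -> dict:
    out = {}
    for mi in MEASURES:
        for mj in MEASURES:
            if mi == mj:
                continue
            try:
                out[f"{mi}->{mj}"] = compute_concordance(
                    patients, mi, mj, cfg.dichotomy
                )
            except Exception as err:  # undefined for empty low groups
                out[f"{mi}->{mj}"] = str(err)
    return out


def write_bundle(bundle: dict, outdir) -> None:
    """Persist the report bundle: every table as CSV plus a JSON summary and
    a JSON-lines stage log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_mod.write_cohort(bundle["cohort"], outdir / "cohort.csv")
    for key, pred in bundle["predictions"].items():
        safe = key.replace("|", "_")
        pred.to_csv(outdir / f"predictions_{safe}.csv", index=False)
    for key, result in bundle["audits"].items():
        safe = key.replace("|", "_")
        for measure, tables in result["measures"].items():
            tables["metrics"].to_csv(
                outdir / f"metrics_{safe}_{measure}.csv", index=False
            )
            tables["baseline_flags"].to_csv(
                outdir / f"baseline_flags_{safe}_{measure}.csv", index=False
            )
    bundle["relative_differences"].to_csv(outdir / "relative_differences.csv")
    summary = {
        "master_seed": bundle["master_seed"],
        "config_hash": bundle["config_hash"],
        "exclusion_ledger": bundle["exclusion_ledger"],
        "descriptives": bundle["descriptives"],
        "concordance": bundle["concordance"],
        "run_meta": bundle["run_meta"],
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    with open(outdir / "log.jsonl", "w") as fh:
        for rec in bundle["log"]:
            fh.write(json.dumps(rec, default=str) + "\n")
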