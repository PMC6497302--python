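"""One-command reproduction of the full synthetic study.

``run_pipeline`` generates a cohort, extracts or takes per-bin
features, and runs the analysis stages in dependency order —
whole-session lasso predictions with permutation nulls, within-session
classification (population / individual / LOO / backtest), the
feature-subset complexity sweep, and peri-event traces — writing tidy
CSV/JSON outputs plus a manifest of config, seeds, and file digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bands import STUDY_SPEC, FeatureSpec
from .features import build_feature_table
from .labeling import LabelConfig, behavior_summary, label_bins
from .perievent import PeriEventConfig, collect_epochs, perievent_average, variance_change
from .sweep import (
    frequency_contribution,
    lasso_survival,
    minimal_model_search,
    prepare_iterations,
    reference_distribution,
    sweep,
    top_tier,
)
from .synth import CohortConfig, cohort_table, generate_cohort, generate_feature_cohort
from .whole_session import (
    CVConfig,
    lasso_cv_predict,
    mwu_to_cohens_d,
    permutation_null,
    rest_normalize,
)
from .within_session import (
    EvalConfig,
    individual_vs_population,
    prefeeding_backtest,
    repeated_eval,
)
from . import io as lio

__all__ = ["PRESETS", "load_config", "run_pipeline"]

logger = logging.getLogger(__name__)

#: built-in run configurations.  ``paper-synthetic`` reproduces the
#: study-shaped cohort (12 animals, four conditions) at desk scale;
#: ``tiny`` is a 3-animal Base-only smoke configuration.
PRESETS: dict[str, dict] = {
    "paper-synthetic": {
        "cohort": {
            "n_animals": 12,
            "conditions": ["Base", "Dep24", "Dep48", "Chow"],
            "n_base_sessions": 2,
            "session_length_s": 1800.0,
            "sampling_rate_hz": 250.0,
            "seed": 7,
        },
        "signal_level": False,
        "eval": {"n_iterations": 10, "seed": 7},
        "cv": {"n_iterations": 20, "seed": 7},
        "n_perm": 20,
        "sweep_ks": [1, 2],
        "dyad_cap": 150,
        "perievent_features": ["SLhg", "CLCRhg"],
        "stages": ["whole_session", "within_session", "sweep", "peri_event"],
    },
    "tiny": {
        "cohort": {
            "n_animals": 3,
            "conditions": ["Base"],
            "n_base_sessions": 1,
            "session_length_s": 900.0,
            "sampling_rate_hz": 250.0,
            "seed": 11,
        },
        "signal_level": True,
        "eval": {"n_iterations": 5, "seed": 11},
        "cv": {"n_iterations": 5, "seed": 11},
        "n_perm": 5,
        "sweep_ks": [1],
        "dyad_cap": 50,
        "perievent_features": ["SLhg"],
        "stages": ["within_session", "sweep", "peri_event"],
    },
}

_KNOWN_KEYS = {
    "cohort", "signal_level", "eval", "cv", "n_perm", "sweep_ks", "dyad_cap",
    "perievent_features", "stages", "exclusions",
}


def load_config(source: dict | str | Path) -> dict:
    """Load and validate a run config (dict, preset name, or YAML path)."""
    if isinstance(source, dict):
        cfg = dict(source)
    elif str(source) in PRESETS:
        cfg = json.loads(json.dumps(PRESETS[str(source)]))
    else:
        cfg = yaml.safe_load(Path(source).read_text())
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cohort_fields = {f.name for f in dataclasses.fields(CohortConfig)}
    bad = set(cfg.get("cohort", {})) - cohort_fields
    if bad:
        raise ValueError(f"unknown cohort config keys: {sorted(bad)}")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, out_dir: Path, seed: int | None = None) -> Path:
    """Execute all configured stages; returns the run directory."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    cohort_kwargs = dict(cfg.get("cohort", {}))
    if seed is not None:
        cohort_kwargs["seed"] = int(seed)
    if "conditions" in cohort_kwargs:
        cohort_kwargs["conditions"] = tuple(cohort_kwargs["conditions"])
    ccfg = CohortConfig(**cohort_kwargs)
    spec = FeatureSpec(exclusions=frozenset(cfg.get("exclusions", []) or STUDY_SPEC.exclusions))
    eval_cfg = EvalConfig(**cfg.get("eval", {}))
    cv_cfg = CVConfig(**cfg.get("cv", {}))
    if seed is not None:
        eval_cfg = replace(eval_cfg, seed=int(seed))
        cv_cfg = replace(cv_cfg, seed=int(seed))
    label_cfg = LabelConfig(bin_length_s=ccfg.bin_length_s)

    logger.info("generating cohort (%d animals, %s)", ccfg.n_animals, ccfg.conditions)
    if cfg.get("signal_level", False):
        sessions = generate_cohort(ccfg, spec)
        for s in sessions:
            table = build_feature_table(s.recording, spec)
            table = label_bins(table, s.intervals, label_cfg)
            table["animal_id"] = s.meta.animal_id
            table["condition"] = s.meta.condition
            table["session_id"] = s.meta.session_id
            s.features = table
            s.recording = None  # free memory once features exist
    else:
        sessions = generate_feature_cohort(ccfg, spec, label_cfg)
    table = cohort_table(sessions)
    table.to_csv(out / "features.csv", index=False)
    feature_names = spec.feature_names()
    stages = cfg.get("stages", [])
    results: dict = {}

    if "whole_session" in stages:
        summaries = []
        for s in sessions:
            try:
                summaries.append(rest_normalize(s.features, feature_names, s.meta))
            except ValueError as e:
                logger.info("session %s excluded from whole-session: %s", s.meta.session_id, e)
        base = [u for u in summaries if u.condition == "Base"]
        if len(base) >= cv_cfg.n_folds:
            X = pd.DataFrame([u.rest_normalized for u in base]).to_numpy()
            y = np.array([u.outcome_grams for u in base])
            dist = lasso_cv_predict(pd.DataFrame(X, columns=feature_names), y, cv_cfg)
            null = permutation_null(X, y, cv_cfg, n_perm=cfg.get("n_perm", 20),
                                    iterations_per_perm=max(1, cv_cfg.n_iterations // 5))
            results["whole_session_grams"] = dist.summary() | {
                "null_mean": float(null.samples.mean()),
                "cohens_d": mwu_to_cohens_d(dist.samples, null.samples),
            }
        pd.DataFrame([
            {"session_id": s.meta.session_id, "voracity":
                behavior_summary(s.intervals, s.meta).voracity_kcal_per_min}
            for s in sessions
        ]).to_csv(out / "behavior_summary.csv", index=False)

    if "within_session" in stages:
        pop = repeated_eval(table, feature_names, eval_cfg)
        results["population_feeding"] = pop.summary()
        base_table = table[table.condition == "Base"]
        try:
            pre = repeated_eval(base_table, feature_names, eval_cfg, positive="prefeed", lag=2.5)
            results["prefeeding"] = pre.summary()
        except ValueError as e:
            logger.warning("prefeeding evaluation skipped: %s", e)
            results["prefeeding"] = None
        back = prefeeding_backtest(base_table, feature_names, eval_cfg, label_cfg)
        back.to_csv(out / "prefeeding_backtest.csv", index=False)
        if ccfg.n_animals >= 3:
            ivp = individual_vs_population(table, feature_names, eval_cfg)
            ivp.to_csv(out / "individual_vs_population.csv", index=False)
            results["individual_minus_population_mean"] = (
                float(ivp.diff_vs_population.mean()) if len(ivp) else None
            )

    if "sweep" in stages:
        base_table = table[table.condition == "Base"] if "Base" in set(table.condition) else table
        iters = prepare_iterations(base_table, feature_names, eval_cfg)
        full_ref = reference_distribution(iters, eval_cfg, "logistic")
        lasso_ref = reference_distribution(iters, eval_cfg, "lasso_logistic")
        sweeps = {}
        for k in cfg.get("sweep_ks", [1]):
            cap = cfg.get("dyad_cap") if k >= 2 else None
            sweeps[k] = sweep(base_table, feature_names, eval_cfg, k, iters=iters, combo_cap=cap)
            st = sweeps[k].table()
            st["top_tier"] = top_tier(sweeps[k])
            st.to_csv(out / f"sweep_k{k}.csv", index=False)
            fc = frequency_contribution(sweeps[k], top_tier(sweeps[k]), spec)
            fc.to_csv(out / f"frequency_contribution_k{k}.csv")
        surv = lasso_survival(iters, eval_cfg, feature_names)
        surv.to_csv(out / "lasso_survival.csv")
        results["minimal_model"] = minimal_model_search(sweeps, full_ref, lasso_ref)
        results["full_logistic"] = full_ref.summary()
        results["lasso_logistic"] = lasso_ref.summary()

    if "peri_event" in stages:
        pcfg = PeriEventConfig(bin_length_s=ccfg.bin_length_s)
        traces = []
        for feat in cfg.get("perievent_features", []):
            mats = []
            for s in sessions:
                al = collect_epochs(s.features, s.intervals, feat, pcfg)
                mats.append(al)
            onset = np.vstack([a.onset for a in mats]) if mats else np.empty((0, 0))
            offset = np.vstack([a.offset for a in mats]) if mats else np.empty((0, 0))
            pooled = dataclasses.replace(
                mats[0], onset=onset, offset=offset
            )
            if len(onset) >= 2:
                tr = perievent_average(pooled)
                tr["feature"] = feat
                traces.append(tr)
                ratio, w, p = variance_change(pooled)
                results[f"variance_ratio_{feat}"] = {"ratio": ratio, "levene_p": p}
        if traces:
            pd.concat(traces).to_csv(out / "perievent_traces.csv", index=False)

    (out / "results.json").write_text(json.dumps(results, indent=1, default=float))
    manifest = {
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "seed": cohort_kwargs.get("seed", ccfg.seed),
        "elapsed_s": round(time.time() - t0, 1),
        "outputs": {p.name: lio.file_digest(p)
                    for p in sorted(set(out.glob("*.csv")) | {out / "results.json"})},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
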