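"""End-to-end pipeline driver.

Runs curation -> featurization -> zero-variance filtering -> splitting ->
scaffold audit -> hyperparameter tuning -> blending -> evaluation on the
testing and independent ligand-validation splits -> per-receptor baselines ->
feature-importance ranking, writing every intermediate artifact plus a
manifest to an output directory. Two presets mirror the two study variants:
``full`` (no Ki column, XGBoost metamodel) and ``ki-filtered`` (Ki
deduplication, Ki feature appended, LightGBM metamodel).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from maap import __version__
from maap.baselines import frequency_baseline, similarity_baseline
from maap.blending import BlendedModel, blended_feature_importance, train_blend
from maap.curation import curate, filter_zero_variance
from maap.features import assemble_features, fit_scaler
from maap.io import FeatureMatrix, InteractionTable, read_interaction_table
from maap.metrics import evaluate
from maap.modeling import CORE_FAMILIES, LearnerSpec, tune
from maap.scaffolds import scaffold_novelty, scaffold_overlap_score, scaffold_profile
from maap.splits import make_splits

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; hashable for reproducibility."""

    interactions_path: str | None = None
    descriptors_path: str | None = None
    embeddings_path: str | None = None
    out_dir: str = "maap_run"
    preset: str = "full"  # full | ki-filtered
    conflict_policy: str = "majority"
    split_seed: int = 0
    model_seed: int = 0
    repeat_seeds: list[int] = field(default_factory=lambda: [0])
    families: list[str] = field(default_factory=lambda: list(CORE_FAMILIES))
    meta_family: str | None = None  # default depends on preset
    budget: int = 8
    objective_mode: str = "cv"
    independent_fraction: float = 0.10
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    log10_ki: bool = False

    @property
    def ki_filter(self) -> bool:
        return self.preset == "ki-filtered"

    def resolved_meta_family(self) -> str:
        if self.meta_family:
            return self.meta_family
        return "lightgbm" if self.ki_filter else "xgboost"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, default=str), encoding="utf-8")


def run_pipeline(config: RunConfig,
                 table: InteractionTable | None = None,
                 descriptors: pd.DataFrame | None = None,
                 embeddings: pd.DataFrame | None = None) -> Path:
    """Execute the full pipeline; returns the artifact directory.

    Inputs may be passed in memory (synthetic fixtures) or read from the
    configured paths. On a stage failure, partial outputs are kept next to a
    FAILED marker naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "load"
    try:
        if table is None:
            table = read_interaction_table(config.interactions_path)
        if descriptors is None:
            descriptors = pd.read_csv(config.descriptors_path, sep="\t")
        if embeddings is None:
            embeddings = pd.read_csv(config.embeddings_path, sep="\t")

        stage = "curate"
        curated, report = curate(table, ki_filter=config.ki_filter,
                                 conflict_policy=config.conflict_policy)
        if len(curated) == 0:
            raise ValueError("curation left no records")
        _write_json(out / "curation_report.json", report.as_dict())

        stage = "featurize"
        X = assemble_features(curated, descriptors, embeddings,
                              include_ki=config.ki_filter, log10_ki=config.log10_ki)
        X = filter_zero_variance(X, scope="descriptor")
        y = curated.labels()

        stage = "split"
        splits = make_splits(curated, seed=config.split_seed,
                             independent_fraction=config.independent_fraction,
                             fractions=config.fractions)
        splits.to_json(out / "split_manifest.json")

        stage = "scaffold_audit"
        smiles = curated.smiles()
        profiles = {name: scaffold_profile([smiles[i] for i in idx])
                    for name, idx in (("train", splits.train),
                                      ("internal_val", splits.internal_val),
                                      ("test", splits.test),
                                      ("independent", splits.independent))}
        audit = {name: p.as_dict() for name, p in profiles.items()}
        audit["independent_novelty_vs_train"] = scaffold_novelty(
            profiles["independent"], profiles["train"])
        audit["overlap_train_vs_independent"] = scaffold_overlap_score(
            profiles["train"], profiles["independent"])
        _write_json(out / "scaffold_audit.json", audit)

        stage = "scale"
        scaler = fit_scaler(X, splits.train)

        stage = "tune"
        from maap.features import apply_scaler
        Xs = apply_scaler(X, scaler)
        X_train, y_train = Xs.values[splits.train], y[splits.train]
        tuned: dict[str, LearnerSpec] = {}
        trial_summary = {}
        for family in config.families:
            kwargs = {}
            if config.objective_mode == "holdout":
                kwargs = dict(X_val=Xs.values[splits.internal_val],
                              y_val=y[splits.internal_val])
            result = tune(family, X_train, y_train, budget=config.budget,
                          seed=config.model_seed,
                          objective_mode=config.objective_mode,
                          refit=False, **kwargs)
            tuned[family] = result.best_spec
            trial_summary[family] = {
                "best_objective": result.best_objective,
                "best_hyperparameters": result.best_spec.hyperparameters,
                "n_trials": len(result.trial_log),
            }
        _write_json(out / "tuning_summary.json", trial_summary)

        stage = "blend"
        meta_family = config.resolved_meta_family()
        per_repeat = {"test": [], "independent": []}
        model = None
        for rep_seed in config.repeat_seeds:
            base_specs = [
                LearnerSpec(f, dict(tuned[f].hyperparameters), seed=rep_seed)
                for f in config.families
            ]
            meta_spec = LearnerSpec(meta_family,
                                    dict(tuned[meta_family].hyperparameters),
                                    seed=rep_seed)
            model = train_blend(base_specs, meta_spec, splits, X, y, scaler=scaler)
            for split_name, idx in (("test", splits.test),
                                    ("independent", splits.independent)):
                pred, proba = model.predict(X.select_rows(idx))
                per_repeat[split_name].append(
                    evaluate(y[idx], pred, scores=proba).as_dict())
        model.save(out / "model_bundle")

        stage = "evaluate"
        for split_name, reports in per_repeat.items():
            _write_json(out / f"evaluation_{split_name}.json",
                        _aggregate(reports))

        stage = "baselines"
        idx_train = splits.train
        sub = lambda idx: InteractionTable([curated.records[i] for i in idx])
        baseline_out = {}
        for split_name, idx in (("test", splits.test),
                                ("independent", splits.independent)):
            freq = frequency_baseline(sub(idx_train), sub(idx),
                                      seed=config.model_seed, mode="sample")
            expected = frequency_baseline(sub(idx_train), sub(idx), mode="expected")
            _, rejected, sim = similarity_baseline(sub(idx_train), sub(idx))
            baseline_out[split_name] = {
                "frequency_sampled": freq.as_dict(),
                "frequency_expected_accuracy": expected,
                "similarity": sim.as_dict(),
                "similarity_rejected": len(rejected),
            }
        _write_json(out / "baseline_report.json", baseline_out)

        stage = "importance"
        top30 = blended_feature_importance(model, top_k=30)
        _write_json(out / "feature_importance_top30.json",
                    [{"feature": n, "importance": v, "role": r}
                     for n, v, r in top30])

        manifest = {
            "version": __version__,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "runtime_seconds": round(time.time() - t0, 2),
            "n_curated_records": len(curated),
            "n_features": X.shape[1],
        }
        _write_json(out / "manifest.json", manifest)
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n",
                                    encoding="utf-8")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc


def _aggregate(reports: list[dict]) -> dict:
    """Mean +/- sd over repeats for every scalar metric; single repeat passes
    through with sd 0."""
    scalars = ["macro_recall", "macro_precision", "macro_f1", "macro_specificity",
               "macro_auc"]
    agg = {"n_repeats": len(reports), "repeats": reports}
    for key in scalars:
        vals = [r[key] for r in reports if r.get(key) is not None]
        if vals:
            agg[key + "_mean"] = float(np.mean(vals))
            agg[key + "_sd"] = float(np.std(vals))
    return agg
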