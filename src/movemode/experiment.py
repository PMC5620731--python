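"""End-to-end experiment orchestration.

Ties the stages together under one seeded configuration: simulate (or
load) trips, build and evaluate a movelet dictionary, extract the
140-feature table, fit reducer-classifier families, and select the
optimal model by the Model Efficiency Metric.  Every artifact is
written as headered delimited text or JSON next to a manifest that
records the configuration, so a rerun with the same configuration
reproduces the outputs exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import features, modeling, movelets, preprocess, synthgen
from .core import Trip

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full experiment run depends on."""

    seed: int = 0
    total_hours: float = 2.0
    # movelet stage
    movelet_H: int = 30
    movelet_delta: int = 5
    keep_fraction: float = 0.5
    # feature/model stage
    rfe_dims: tuple[int, ...] = tuple(range(1, 31))
    pca_variance_cap: float = 0.95
    classifiers: tuple[str, ...] = ("rf", "knn")
    reducers: tuple[str, ...] = ("rfe", "pca")
    rf_trees: int = modeling.RF_TREES
    cv_trees: int | None = 100
    folds: int = 10
    split_unit: str = "row"  # "row" (window level) or "trip"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        movelets.MoveletConfig(H=self.movelet_H, delta=self.movelet_delta)
        if not 0 < self.keep_fraction <= 1:
            raise ValueError("keep_fraction must be in (0, 1]")
        if self.split_unit not in ("row", "trip"):
            raise ValueError("split_unit must be 'row' or 'trip'")
        for c in self.classifiers:
            if c not in ("rf", "knn"):
                raise ValueError(f"unknown classifier {c!r}")


def _split_indices(n: int, seed: int) -> dict:
    assignment = preprocess.split_dataset(range(n), seed=seed).assignment
    return {
        part: np.array([i for i in range(n) if assignment[i] == part], dtype=int)
        for part in ("train", "validation", "test")
    }


def run_movelet_stage(
    trips: list[Trip],
    config: movelets.MoveletConfig,
    seed: int,
    keep_fraction: float = 0.5,
    split_unit: str = "row",
) -> dict:
    """Generate, split, refine and evaluate a movelet dictionary.

    With ``split_unit='row'`` individual movelets are randomly assigned
    60/20/20 to train/validation/test (the default; note overlapping
    windows make this split optimistic — see the package docs).  With
    ``'trip'`` whole trips are assigned instead.
    """
    all_movelets = movelets.generate_movelets(trips, config)
    if split_unit == "trip":
        assignment = preprocess.split_dataset([t.trip_id for t in trips], seed=seed).assignment
        parts = {
            part: [m for m in all_movelets if assignment[m.trip_id] == part]
            for part in ("train", "validation", "test")
        }
    else:
        idx = _split_indices(len(all_movelets), seed)
        parts = {part: [all_movelets[i] for i in idx[part]] for part in idx}
    dictionary = movelets.train_dictionary(
        parts["train"], parts["validation"], config, keep_fraction
    )
    test_scaled = dictionary.scaler.transform_all(parts["test"])
    confusion, accuracy = movelets.evaluate_movelets(dictionary, test_scaled)
    return {
        "dictionary": dictionary,
        "confusion": confusion,
        "accuracy": accuracy,
        "n_movelets": {part: len(v) for part, v in parts.items()},
        "test": test_scaled,
    }


def run_feature_stage(trips: list[Trip], cfg: RunConfig) -> dict:
    """Feature table, model families, and per-family optimal selection."""
    table = features.build_feature_table(trips)
    return fit_families(table, cfg)


def fit_families(table: pd.DataFrame, cfg: RunConfig) -> dict:
    """Split a feature table and fit every configured model family."""
    if table.empty:
        raise ValueError("feature stage: no trips long enough to produce feature rows")
    cols = features.feature_columns()
    if cfg.split_unit == "trip":
        assignment = preprocess.split_dataset(sorted(table["trip_id"].unique()), seed=cfg.seed).assignment
        part_of = table["trip_id"].map(assignment)
    else:
        idx = _split_indices(len(table), cfg.seed)
        part_of = pd.Series("", index=table.index)
        for part, ii in idx.items():
            part_of.iloc[ii] = part
    X = {p: table.loc[part_of == p, cols] for p in ("train", "validation", "test")}
    y = {p: table.loc[part_of == p, "mode"].to_numpy() for p in ("train", "validation", "test")}

    families: dict = {}
    reducers: dict = {}
    rfe_reducer = None
    for red in cfg.reducers:
        for clf in cfg.classifiers:
            key = f"{red}_{clf}"
            if red == "rfe":
                fits, rfe_reducer, _ = modeling.fit_rfe_family(
                    X["train"], y["train"], clf, dims=cfg.rfe_dims, seed=cfg.seed,
                    folds=cfg.folds, rf_trees=cfg.rf_trees, cv_trees=cfg.cv_trees,
                    X_test=X["test"], y_test=y["test"], reducer=rfe_reducer,
                )
                reducers[key] = rfe_reducer
            else:
                fits, pca_red, _ = modeling.fit_pca_family(
                    X["train"], y["train"], clf, variance_cap=cfg.pca_variance_cap,
                    seed=cfg.seed, folds=cfg.folds, rf_trees=cfg.rf_trees,
                    cv_trees=cfg.cv_trees, X_test=X["test"], y_test=y["test"],
                )
                reducers[key] = pca_red
            families[key] = fits
    selections = {key: modeling.select_optimal(fits) for key, fits in families.items()}
    return {
        "table": table,
        "families": families,
        "selections": selections,
        "reducers": reducers,
        "split": {p: int((part_of == p).sum()) for p in ("train", "validation", "test")},
    }


def family_frame(fits: list[modeling.ModelFit]) -> pd.DataFrame:
    """Accuracy/MEM curve of a family as a plain table."""
    return pd.DataFrame(
        {
            "dim": [f.dim for f in fits],
            "alpha": [f.alpha for f in fits],
            "gamma": [f.gamma for f in fits],
            "mem": [f.mem for f in fits],
            "test_accuracy": [f.test_accuracy for f in fits],
        }
    )


def run_experiment(cfg: RunConfig, outdir, trips: list[Trip] | None = None) -> dict:
    """Run every stage and write artifacts under ``outdir``.

    When ``trips`` is omitted a synthetic dataset is simulated from the
    configuration's seed and total volume.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if trips is None:
        sim_cfg = synthgen.SimConfig(total_hours=cfg.total_hours, seed=cfg.seed)
        trips, sim_manifest = synthgen.simulate_dataset(sim_cfg)
    else:
        sim_manifest = {"source": "user-supplied trips", "n_trips": len(trips)}

    logger.info("movelet stage: H=%d delta=%d", cfg.movelet_H, cfg.movelet_delta)
    mov = run_movelet_stage(
        trips,
        movelets.MoveletConfig(H=cfg.movelet_H, delta=cfg.movelet_delta),
        seed=cfg.seed,
        keep_fraction=cfg.keep_fraction,
        split_unit=cfg.split_unit,
    )
    mov["confusion"].to_csv(outdir / "movelet_confusion.csv")
    mov["dictionary"].save(outdir / "dictionary")

    logger.info("feature stage: %d trips", len(trips))
    feat = run_feature_stage(trips, cfg)
    feat["table"].to_csv(outdir / "feature_table.csv", index=False)
    report: dict = {
        "movelet_accuracy": mov["accuracy"],
        "families": {},
    }
    for key, fits in feat["families"].items():
        family_frame(fits).to_csv(outdir / f"family_{key}.csv", index=False)
        sel = feat["selections"][key]
        chosen = sel.chosen
        if chosen.test_confusion is not None:
            chosen.test_confusion.to_csv(outdir / f"confusion_{key}_{chosen.dim}.csv")
        report["families"][key] = {
            "chosen_dim": chosen.dim,
            "alpha": chosen.alpha,
            "gamma": chosen.gamma,
            "mem": chosen.mem,
            "alpha_max": sel.alpha_max,
            "test_accuracy": chosen.test_accuracy,
        }

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "simulation": sim_manifest,
        "split_sizes": feat["split"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (outdir / "selection_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return {"movelets": mov, "features": feat, "report": report}
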