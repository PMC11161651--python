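"""End-to-end orchestration: generate -> preprocess -> design -> train ->
ensemble -> explain -> validate -> aggregate, with a manifest for exact
reruns.

The run configuration aggregates every stage's parameters and a master
seed; all per-stage seeds are derived deterministically from it.  A run
writes its artifacts (dataset, metrics, relevance maps, perturbation
table, beat summaries) plus ``manifest.json`` into the output
directory.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .architecture import LONG_STRIDES, R_LONG, R_SHORT, SHORT_STRIDES, SolverConstraints, solve_configuration
from .beats import class_aggregate, summarize_record
from .perturbation import compare_methods
from .preprocess import PreprocessConfig, preprocess_records
from .records import LABELS, save_dataset
from .synthetic import GeneratorConfig, generate_dataset, train_test_split_records
from .training import (
    EnsembleModel,
    evaluate,
    optimize_ensemble_weight,
    train_model,
)
from .xai import METHOD_NAMES, explain

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    r_short: int = R_SHORT
    r_long: int = R_LONG
    n_layers: int = 9
    f_last: int = 8
    n_per_class: int = 40
    test_fraction: float = 0.2
    n_folds: int = 2
    epochs: int = 10
    batch_short: int = 32
    batch_long: int = 8
    lr_short: float = 1e-3
    lr_long: float = 1e-3
    xai_methods: tuple[str, ...] = ("dtd", "itg")
    n_explain: int = 10
    perturbation_step: float = 0.05
    seed: int = 0
    out_dir: str = "runs/default"

    @classmethod
    def smoke(cls, seed: int = 0, out_dir: str = "runs/smoke") -> "RunConfig":
        return cls(n_per_class=40, epochs=3, seed=seed, out_dir=out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorConfig(**data.pop("generator", {}))
        pre = PreprocessConfig(**data.pop("preprocess", {}))
        if "xai_methods" in data:
            data["xai_methods"] = tuple(data["xai_methods"])
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(generator=gen, preprocess=pre, **data)


def _spec_pair(config: RunConfig):
    short = solve_configuration(
        SolverConstraints(target_r=config.r_short, n_layers=config.n_layers,
                          strides=SHORT_STRIDES if config.n_layers == 9 else None),
        f_last=config.f_last,
    )
    long = solve_configuration(
        SolverConstraints(target_r=config.r_long, n_layers=config.n_layers,
                          strides=LONG_STRIDES if config.n_layers == 9 else None),
        f_last=config.f_last,
    )
    return short, long


def run_pipeline(config: RunConfig, log=print) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "stages": {},
    }
    stage = "generate"
    try:
        t0 = time.time()
        records = generate_dataset(config.generator, config.n_per_class, config.seed)
        save_dataset(records, out / "dataset")
        manifest["stages"]["generate"] = {"n_records": len(records)}

        stage = "preprocess"
        records = preprocess_records(records, config.preprocess)

        stage = "design"
        spec_short, spec_long = _spec_pair(config)
        (out / "spec_short.json").write_text(spec_short.to_json())
        (out / "spec_long.json").write_text(spec_long.to_json())
        manifest["stages"]["design"] = {
            "r_short": spec_short.receptive_field,
            "r_long": spec_long.receptive_field,
        }

        stage = "split"
        folds, test = train_test_split_records(
            records, config.test_fraction, config.n_folds, config.seed
        )

        stage = "train"
        fold_pairs, val_folds = [], []
        for k in range(config.n_folds):
            train_recs = [r for j, f in enumerate(folds) if j != k for r in f]
            short, res_s = train_model(
                spec_short, train_recs, folds[k], batch_size=config.batch_short,
                learning_rate=config.lr_short, seed=config.seed + 100 + k,
                epochs=config.epochs, fold=k,
            )
            long, res_l = train_model(
                spec_long, train_recs, folds[k], batch_size=config.batch_long,
                learning_rate=config.lr_long, seed=config.seed + 200 + k,
                epochs=config.epochs, fold=k,
            )
            log(f"fold {k}: short F1={res_s.f1:.1f} long F1={res_l.f1:.1f}")
            fold_pairs.append((short, long))
            val_folds.append(folds[k])

        stage = "ensemble"
        weights = optimize_ensemble_weight(fold_pairs, val_folds)
        ensemble = EnsembleModel(*fold_pairs[0], weights)
        metrics = {
            "short": evaluate(fold_pairs[0][0], test),
            "long": evaluate(fold_pairs[0][1], test),
            "ensemble": evaluate(ensemble, test),
            "w_long": weights.w_long,
        }
        manifest["stages"]["train"] = metrics
        log(f"test F1: short={metrics['short']['f1']:.1f} "
            f"long={metrics['long']['f1']:.1f} ensemble={metrics['ensemble']['f1']:.1f} "
            f"(w_long={weights.w_long:.4f})")

        stage = "explain"
        subset = test[: config.n_explain]
        background = records[:50]
        maps = {}
        for meth in config.xai_methods:
            maps[meth] = [
                explain(fold_pairs[0][0], r, meth, seed=config.seed, background=background)
                for r in subset
            ]
        np.savez_compressed(
            out / "relevance.npz",
            **{
                f"{meth}_{i}": m.values
                for meth, lst in maps.items()
                for i, m in enumerate(lst)
            },
        )
        manifest["stages"]["explain"] = {"methods": list(config.xai_methods),
                                         "n_records": len(subset)}

        stage = "validate-xai"
        table = compare_methods(
            {"short": fold_pairs[0][0]},
            subset,
            methods=tuple(config.xai_methods),
            step=config.perturbation_step,
            seed=config.seed,
            background=background,
        )
        table.to_csv(out / "perturbation_auc.csv", index=False)
        manifest["stages"]["validate_xai"] = {"n_cells": len(table)}

        stage = "aggregate"
        meth0 = config.xai_methods[0]
        summaries = [
            summarize_record(r, m) for r, m in zip(subset, maps[meth0])
        ]
        agg = {}
        for label in LABELS:
            try:
                s = class_aggregate(summaries, label)
            except ValueError:
                continue
            agg[label] = {"n_records": s.n_records}
            np.savez_compressed(
                out / f"beats_{label.replace('-', '')}.npz",
                template=s.template, mean_relevance=s.mean_relevance,
                intra_ecg_cv=s.intra_ecg_cv,
            )
        manifest["stages"]["aggregate"] = agg
        manifest["elapsed_s"] = round(time.time() - t0, 2)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
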