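"""Grid runner over {number of end-systems} x {split ratio}.

Reproduces the structure of the study's imbalance experiments: for each
client count the three canonical ratios (equal, imbalanced, extreme), nine
cells in total by default, each trained end-to-end on a shared dataset with
a common stratified held-out split.  Results are written as a tidy CSV plus
a pivoted table (columns = ratio within client count, row = final metric),
both byte-reproducible under a fixed seed; completed cells are skipped on
rerun via on-disk markers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .models import builtin_spec
from .partition import parse_ratio, stratified_partition, train_test_indices
from .protocol import TrainConfig, train
from .synthetic import make_image_set

__all__ = ["GridSpec", "GridResult", "DEFAULT_RATIOS", "run_grid", "summarize"]

logger = logging.getLogger(__name__)

DEFAULT_RATIOS: dict[int, list[str]] = {
    3: ["1:1:1", "7:2:1", "8:1:1"],
    4: ["1:1:1:1", "4:3:2:1", "7:1:1:1"],
    5: ["1:1:1:1:1", "4:2:2:1:1", "6:1:1:1:1"],
}


@dataclass
class GridSpec:
    """One experiment grid: dataset, model, cells, seeds."""

    model: str = "covid"
    client_counts: list[int] = field(default_factory=lambda: [3, 4, 5])
    ratios: dict[int, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_RATIOS.items()})
    seeds: list[int] = field(default_factory=lambda: [0])
    epochs: int = 10
    # synthetic dataset defaults (used when no dataset is supplied)
    n_samples: int = 400
    image_size: int = 32
    lesion_contrast: float = 0.5
    noise_sd: float = 0.1
    cholesterol_noise_sd: float = 5.0
    global_batch_size: int | None = 64
    optimizer: dict[str, float] = field(default_factory=dict)
    test_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not self.client_counts:
            raise ValueError("grid is empty")
        for k in self.client_counts:
            if k not in self.ratios or not self.ratios[k]:
                raise ValueError(f"no ratios configured for {k} clients")
            for r in self.ratios[k]:
                if parse_ratio(r).n_clients != k:
                    raise ValueError(f"ratio {r!r} does not have {k} shares")

    def cells(self) -> list[tuple[int, str, int]]:
        return [
            (k, ratio, seed)
            for k in self.client_counts
            for ratio in self.ratios[k]
            for seed in self.seeds
        ]

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GridSpec":
        d = dict(d)
        if "ratios" in d:
            d["ratios"] = {int(k): list(v) for k, v in d["ratios"].items()}
        return cls(**d)


@dataclass
class GridResult:
    frame: pd.DataFrame  # one row per (count, ratio, seed)
    aggregate: pd.DataFrame  # mean/sd across seeds per (count, ratio)
    metric_name: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.frame["metric_value"].to_numpy(dtype=float))):
            raise ValueError("non-finite metrics in grid result")


def _make_dataset(grid: GridSpec, seed: int):
    spec_name = grid.model
    if spec_name in ("covid", "mura"):
        ds = make_image_set(
            grid.n_samples,
            grid.image_size,
            lesion_contrast=grid.lesion_contrast,
            noise_sd=grid.noise_sd,
            seed=seed,
        )
        return ds.images, ds.labels
    from .synthetic import make_cholesterol_set

    ds = make_cholesterol_set(grid.n_samples, noise_sd=grid.cholesterol_noise_sd, seed=seed)
    x = ds.table[["age", "sex", "height", "weight", "TC", "HDL_C", "TG"]].to_numpy(dtype=float)
    y = ds.table["LDL_C"].to_numpy(dtype=float)
    return x, y


def _cell_name(count: int, ratio: str, seed: int) -> str:
    return f"cell_{count}_{ratio.replace(':', '-')}_{seed}"


def run_grid(
    grid: GridSpec,
    out_dir: str | Path,
    dataset: tuple[np.ndarray, np.ndarray] | None = None,
    master_seed: int = 0,
) -> GridResult:
    """Run every grid cell; resume from on-disk markers; write CSV outputs.

    Each cell: stratified 20% test split -> partition the training set by
    the cell's ratio -> split training -> final held-out metric.  Cell
    failures are recorded and the remaining cells continue.
    """
    out_dir = Path(out_dir)
    cell_dir = out_dir / "cells"
    cell_dir.mkdir(parents=True, exist_ok=True)

    spec = builtin_spec(grid.model)
    overrides: dict[str, Any] = {}
    if spec.task == "classification":
        overrides["input_shape"] = (grid.image_size, grid.image_size, 1)
    if grid.global_batch_size:
        overrides["global_batch_size"] = grid.global_batch_size
    if overrides:
        spec = spec.replace(**overrides)

    if dataset is None:
        dataset = _make_dataset(grid, master_seed)
    x_all, y_all = dataset
    labels_for_split = y_all if spec.task == "classification" else None
    train_idx, test_idx = train_test_indices(
        labels_for_split, x_all.shape[0], grid.test_fraction, seed=master_seed
    )
    x_train, y_train = x_all[train_idx], y_all[train_idx]
    eval_set = (x_all[test_idx], y_all[test_idx])

    rows = []
    failures = []
    for count, ratio_text, seed in grid.cells():
        marker = cell_dir / f"{_cell_name(count, ratio_text, seed)}.json"
        if marker.exists():
            rows.append(json.loads(marker.read_text()))
            logger.info("skipping completed cell %s", marker.stem)
            continue
        try:
            ratio = parse_ratio(ratio_text)
            part_labels = y_train if spec.task == "classification" else None
            partition = stratified_partition(part_labels, x_train.shape[0], ratio, seed=seed)
            config = TrainConfig(
                spec=spec,
                partition=partition,
                optimizer=dict(grid.optimizer),
                seed=seed,
                epochs=grid.epochs,
            )
            history, _ = train(config, x_train, y_train, eval_set=eval_set)
            if history.rows and "metric_value" in history.rows[-1]:
                final = history.rows[-1]
            else:
                # epochs == 0: report the untrained model's metric
                from .protocol import evaluate as _evaluate
                from .models import build_split_model

                model, cp, sp = build_split_model(spec, seed)
                metric = _evaluate(model, cp, sp, eval_set, spec, scaler=None)
                final = {
                    "train_loss": float("nan"),
                    "metric_name": metric.name,
                    "metric_value": metric.value,
                }
            history_path = cell_dir / f"{_cell_name(count, ratio_text, seed)}_history.csv"
            if history.rows:
                frame = history.to_frame().drop(columns=["seconds"])
                frame.to_csv(history_path, index=False, float_format="%.8f")
            row = {
                "n_clients": count,
                "ratio": ratio_text,
                "seed": seed,
                "final_loss": final.get("train_loss", float("nan")),
                "metric_name": final["metric_name"],
                "metric_value": final["metric_value"],
                "history": str(history_path.name),
            }
            marker.write_text(json.dumps(row, sort_keys=True))
            rows.append(row)
            logger.info(
                "cell %d clients %s seed %d: %s=%.4f",
                count,
                ratio_text,
                seed,
                row["metric_name"],
                row["metric_value"],
            )
        except Exception as exc:  # cell failure: record, continue
            failures.append({"n_clients": count, "ratio": ratio_text, "seed": seed, "error": str(exc)})
            logger.error("cell %d/%s/%d failed: %s", count, ratio_text, seed, exc)

    if failures:
        (out_dir / "failures.json").write_text(json.dumps(failures, indent=2))
    if not rows:
        raise RuntimeError(f"all {len(grid.cells())} grid cells failed")

    columns = ["n_clients", "ratio", "seed", "final_loss", "metric_name", "metric_value", "history"]
    frame = (
        pd.DataFrame(rows)[columns]
        .sort_values(["n_clients", "ratio", "seed"])
        .reset_index(drop=True)
    )
    metric_name = frame["metric_name"].iloc[0]
    aggregate = (
        frame.groupby(["n_clients", "ratio"], sort=True)["metric_value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    frame.to_csv(out_dir / "grid_results.csv", index=False, float_format="%.6f")

    # pivoted table: one metric row, columns are ratio-within-count
    order = [(k, r) for k in grid.client_counts for r in grid.ratios[k]]
    cols, vals = [], []
    for k, r in order:
        sub = aggregate[(aggregate["n_clients"] == k) & (aggregate["ratio"] == r)]
        if len(sub):
            cols.append(f"{k} end-systems {r}")
            vals.append(float(sub["mean"].iloc[0]))
    pivot = pd.DataFrame([vals], columns=cols, index=[metric_name])
    pivot.to_csv(out_dir / "grid_table.csv", float_format="%.6f", index_label="metric")

    return GridResult(frame, aggregate, metric_name)


def _imbalance(ratio_text: str) -> float:
    shares = np.asarray(parse_ratio(ratio_text).shares, dtype=float)
    shares = shares / shares.sum()
    return float(shares.var())


def summarize(result: GridResult) -> tuple[pd.DataFrame, str]:
    """Rank cells and name the best one.

    The best cell maximizes accuracy (or minimizes RMSLE); ties break toward
    more clients, then toward more imbalance — favoring the configuration
    that lets the most hospitals participate.  Returns the annotated
    aggregate table (with a delta-to-best column) and a markdown summary.
    """
    agg = result.aggregate.copy()
    if len(agg) == 0:
        raise ValueError("empty grid result")
    higher_is_better = result.metric_name != "rmsle"
    agg["_imbalance"] = [_imbalance(r) for r in agg["ratio"]]
    agg["_score"] = agg["mean"] if higher_is_better else -agg["mean"]
    ranked = agg.sort_values(
        by=["_score", "n_clients", "_imbalance"], ascending=False, kind="stable"
    )
    best = ranked.iloc[0]
    agg["delta_to_best"] = (best["mean"] - agg["mean"]) if higher_is_better else (
        agg["mean"] - best["mean"]
    )
    agg = agg.drop(columns=["_imbalance", "_score"])
    lines = [
        f"# Grid summary ({result.metric_name})",
        "",
        f"Best cell: **{int(best['n_clients'])} end-systems, ratio {best['ratio']}** "
        f"with mean {result.metric_name} = {best['mean']:.4f}",
        "",
        "```",
        agg.to_string(index=False),
        "```",
    ]
    return agg, "\n".join(lines)
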