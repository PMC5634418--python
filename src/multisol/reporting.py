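"""Figure/table rendering and end-to-end pipeline orchestration.

Every number shown in a plot is also written to a machine-readable TSV;
plots are optional so the numeric pipeline runs headless.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, replace
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap

from . import __version__
from . import data_io
from .dataset import ExpressionDataset
from .elm_classifier import DifferenceMatrix, ELMConfig, weight_difference
from .feature_ranking import rank_features
from .multiplicity_screen import ScreenConfig, best_pair, run_screen
from .splits_metrics import SplitSpec
from .triplet_screen import METRICS, TripletRecord, screen_triplets

log = logging.getLogger(__name__)

_WHITE_RED = LinearSegmentedColormap.from_list("white_red", ["white", "red"])


def heatmap(diff: DifferenceMatrix, path: str | Path) -> Path:
    """Render a difference matrix: white = 0, red = max_difference."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(8, 5))
    vmax = diff.max_difference if diff.max_difference > 0 else 1.0
    im = ax.imshow(diff.values, cmap=_WHITE_RED, vmin=0.0, vmax=vmax, aspect="auto")
    fig.colorbar(im, ax=ax, label="|weight difference|")
    ax.set_xlabel("input feature")
    ax.set_ylabel("hidden unit")
    ax.set_title(f"max difference = {diff.max_difference:.3g}")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def scatter3d(
    records: Sequence[TripletRecord], metric: str, path: str | Path
) -> Path:
    """3-D scatter of triplet ranks (x, y, z), colored by a metric.

    Writes a sibling ``.caption.txt`` documenting the color scale and a
    ``.tsv`` with the plotted coordinates.
    """
    if not records:
        raise ValueError("no records to plot")
    path = Path(path)
    xs = [r.ranks[0] for r in records]
    ys = [r.ranks[1] for r in records]
    zs = [r.ranks[2] for r in records]
    vals = [r.metrics.metric(metric) for r in records]
    vals = [v if v is not None else np.nan for v in vals]

    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    sc = ax.scatter(xs, ys, zs, c=vals, cmap="coolwarm", depthshade=False)
    fig.colorbar(sc, ax=ax, label=metric, shrink=0.7)
    ax.set_xlabel("x (rank)")
    ax.set_ylabel("y (rank)")
    ax.set_zlabel("z (rank)")
    fig.savefig(path, dpi=120)
    plt.close(fig)

    lo, hi = np.nanmin(vals), np.nanmax(vals)
    path.with_suffix(".caption.txt").write_text(
        f"Triplet ranks x <= y <= z colored by {metric}; "
        f"color scale spans {lo:.3f} (blue) to {hi:.3f} (red).\n"
    )
    export_scatter_coords(records, metric, path.with_suffix(".tsv"))
    return path


def export_scatter_coords(
    records: Sequence[TripletRecord], metric: str, path: str | Path
) -> Path:
    rows = [
        {"x": r.ranks[0], "y": r.ranks[1], "z": r.ranks[2],
         metric: r.metrics.metric(metric)}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")
    return Path(path)


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_manifest(
    matrix_path: str | Path,
    labels_path: str | Path,
    config: dict,
) -> dict:
    return {
        "software_version": __version__,
        "inputs": {
            "matrix": str(matrix_path),
            "labels": str(labels_path),
            "matrix_sha256": _digest(matrix_path),
            "labels_sha256": _digest(labels_path),
        },
        "config": config,
    }


DEFAULT_PIPELINE_CONFIG = {
    "seed": 0,
    "positive_class": None,
    "screen": {
        "mode": "Top20Features",
        "n_runs": 500,
        "cutoff": 0.9,
        "train_fraction": 0.7,
    },
    "triplets": {
        "k": 50,
        "cutoffs": {"accuracy": 0.9, "precision": 0.9, "recall": 0.9},
        "n_hidden": 150,
        "train_fraction": 0.8,
    },
    "skip_plots": False,
}


def _merged(overrides: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_PIPELINE_CONFIG))  # deep copy
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def full_pipeline(
    matrix_path: str | Path,
    labels_path: str | Path,
    out_dir: str | Path,
    config: dict | None = None,
) -> Path:
    """Run ranking, the model screen, the best-pair comparison and the
    triplet screen; write every artifact (manifest, TSVs, optional plots)
    into ``out_dir``.  Deterministic given the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = _merged(config)
    seed = int(cfg["seed"])

    manifest = build_manifest(matrix_path, labels_path, cfg)
    data_io.write_manifest(manifest, out / "manifest.json")

    def stage(name):
        log.info("pipeline stage: %s", name)
        return name

    try:
        stage("load")
        ds = data_io.read_dataset(
            matrix_path, labels_path, positive_class=cfg["positive_class"]
        )

        stage("rank")
        rf = rank_features(ds)
        rf.to_tsv(out / "ranked_features.tsv")

        stage("model_screen")
        sc = cfg["screen"]
        screen_config = ScreenConfig(
            mode=sc["mode"],
            n_runs=int(sc["n_runs"]),
            cutoff=float(sc["cutoff"]),
            split_spec=SplitSpec(
                train_fraction=float(sc["train_fraction"]), seed=seed
            ),
            base_seed=seed,
        )
        screen_report = run_screen(ds, screen_config)
        data_io.write_report_table(screen_report, out / "model_screen.tsv")
        pd.DataFrame(
            screen_report.per_run_log, columns=["seed", "accuracy"]
        ).to_csv(out / "model_screen_runs.tsv", sep="\t", index=False,
                 float_format="%.17g")

        stage("best_pair")
        a, b = best_pair(screen_report, tiebreak_seed=seed)
        diff = weight_difference(a, b)
        diff.to_tsv(out / "best_pair_difference.tsv")
        if not cfg["skip_plots"]:
            heatmap(diff, out / "best_pair_difference.png")

        stage("triplet_screen")
        tc = cfg["triplets"]
        k = min(int(tc["k"]), ds.n_features)
        triplet_report = screen_triplets(
            ds,
            rf,
            k=k,
            cutoffs=tc["cutoffs"],
            elm_config=ELMConfig(n_hidden=int(tc["n_hidden"]), seed=seed),
            split_spec=SplitSpec(
                train_fraction=float(tc["train_fraction"]), seed=seed
            ),
        )
        data_io.write_report_table(triplet_report, out / "triplet_screen.tsv")
        triplet_report.to_tsv(out / "triplet_records.tsv")
        for metric in METRICS:
            export_scatter_coords(
                triplet_report.records, metric, out / f"triplet_scatter_{metric}.tsv"
            )
            if not cfg["skip_plots"]:
                scatter3d(
                    triplet_report.records,
                    metric,
                    out / f"triplet_scatter_{metric}.png",
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    return out


def rerun_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> Path:
    """Reproduce a pipeline run from its manifest."""
    manifest = data_io.read_manifest(manifest_path)
    return full_pipeline(
        manifest["inputs"]["matrix"],
        manifest["inputs"]["labels"],
        out_dir,
        config=manifest["config"],
    )
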