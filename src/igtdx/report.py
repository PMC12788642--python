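"""Benchmark orchestration and diagnostic visuals.

``run_benchmark`` drives simulate -> convert -> evaluate over a grid of
(simulation model, distance metric) cells and returns a results table of
"mean (sd)" strings for the four validation indices, mirroring the
simulation-study layout.  The rendering helpers draw rank-matrix heatmaps
(grey level = rank, dark = small by default) and class-wise pseudo-image
panels.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cnn import CNNSpec, CVReport, INDEX_NAMES, cross_validate
from .io import PseudoImageSet
from .layout import RankMatrix, convert
from .simulate import MODELS, SimSpec, simulate

__all__ = ["RunManifest", "render_rank_heatmap", "render_class_panels", "run_benchmark"]


@dataclass
class RunManifest:
    """Provenance for one benchmark cell: config, files, hashes, timing."""

    model: str
    metric: str
    seed: int
    config: dict[str, Any] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)
    hashes: dict[str, str] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0
    version: str = ""

    def add_file(self, role: str, path: str | Path) -> None:
        path = Path(path)
        self.files[role] = str(path)
        self.hashes[role] = hashlib.sha256(path.read_bytes()).hexdigest()

    def verify(self) -> bool:
        return all(
            Path(p).exists()
            and hashlib.sha256(Path(p).read_bytes()).hexdigest() == self.hashes[role]
            for role, p in self.files.items()
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


def render_rank_heatmap(
    R: RankMatrix | np.ndarray,
    out: str | Path,
    dark_small: bool = True,
    margin: int = 0,
) -> Path:
    """Grayscale heatmap of a rank matrix; rank 1 darkest by default.

    Writes an exact p x p pixel PNG (one pixel per matrix entry, linear
    gray map), padded by ``margin`` white pixels on each side if
    requested.
    """
    from PIL import Image

    M = (R.R if isinstance(R, RankMatrix) else np.asarray(R)).astype(float)
    hi = M.max() or 1.0
    gray = M / hi
    if not dark_small:
        gray = 1.0 - gray
    img = np.floor(gray * 255.0 + 0.5).clip(0, 255).astype(np.uint8)
    if margin:
        img = np.pad(img, margin, constant_values=255)
    Image.fromarray(img, mode="L").save(out)
    return Path(out)


def render_class_panels(
    image_sets: PseudoImageSet | list[PseudoImageSet],
    out: str | Path,
    titles: list[str] | None = None,
) -> Path:
    """Two-row panel: first class-0 sample on top, first class-1 below.

    With several image sets (e.g. one per metric) each set becomes a
    column.  Representative samples are the first of each class by index.
    """
    sets = [image_sets] if isinstance(image_sets, PseudoImageSet) else list(image_sets)
    for s in sets:
        if len(np.unique(s.y)) < 2:
            raise ValueError("both classes must be present in every image set")
    ncol = len(sets)
    fig, axes = plt.subplots(2, ncol, figsize=(2.2 * ncol, 4.6), squeeze=False)
    for j, s in enumerate(sets):
        for cls in (0, 1):
            idx = int(np.flatnonzero(s.y == cls)[0])
            ax = axes[cls][j]
            ax.imshow(s.images[idx], cmap="gray", vmin=0, vmax=1, interpolation="nearest")
            ax.set_xticks([])
            ax.set_yticks([])
            if cls == 0 and titles:
                ax.set_title(titles[j], fontsize=9)
            if j == 0:
                ax.set_ylabel(f"class {cls}")
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(out)


def run_benchmark(
    models: list[str] | None = None,
    metrics: list[str] | None = None,
    seed: int = 0,
    grid_shape: tuple[int, int] = (50, 50),
    sim_overrides: dict[str, Any] | None = None,
    cnn_spec: CNNSpec | None = None,
    folds: int = 10,
    repeats: int = 1,
    max_steps: int = 3000,
    stall_limit: int = 200,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Run the (model x metric) benchmark grid.

    For each cell: simulate the model dataset, build the metric's layout
    at ``grid_shape``, evaluate with repeated stratified k-fold CV, and
    record the four validation indices.  Returns a nested dict
    ``{model: {metric: {"cells": {...}, "raw": CVReport-summary}}}``; a
    failing cell raises with the (model, metric) pair named.
    """
    models = models or list(MODELS)
    metrics = metrics or ["ED", "RD", "GD", "JD", "WD", "TD"]
    sim_overrides = sim_overrides or {}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    results: dict[str, Any] = {}
    for model in models:
        spec = SimSpec(model_name=model, seed=seed, **sim_overrides)
        ds = simulate(spec)
        results[model] = {}
        for metric in metrics:
            manifest = RunManifest(
                model=model, metric=metric, seed=seed,
                config={"grid_shape": list(grid_shape), "folds": folds,
                        "repeats": repeats, "max_steps": max_steps},
                started=time.time(),
            )
            try:
                layout, imgs = convert(
                    ds, metric=metric, grid_shape=grid_shape,
                    max_steps=max_steps, stall_limit=stall_limit, seed=seed,
                )
                report: CVReport = cross_validate(
                    imgs, cnn_spec, folds=folds, repeats=repeats, seed=seed
                )
            except Exception as exc:  # identify the failing cell
                raise RuntimeError(f"benchmark cell ({model}, {metric}) failed: {exc}") from exc
            manifest.finished = time.time()
            cell = {name: report.cell(name) for name in INDEX_NAMES}
            results[model][metric] = {"cells": cell, "raw": report.summary()}
            if out_dir is not None:
                stem = out_dir / f"{model}_{metric}"
                layout.to_json(stem.with_suffix(".layout.json"))
                manifest.add_file("layout", stem.with_suffix(".layout.json"))
                manifest.to_json(stem.with_suffix(".manifest.json"))
                with open(out_dir / "runs.jsonl", "a") as fh:
                    fh.write(json.dumps({
                        "model": model, "metric": metric, "seed": seed,
                        "elapsed_s": round(manifest.finished - manifest.started, 2),
                        "final_err": int(layout.error_trace[-1]),
                        "accuracy": report.mean("accuracy"),
                    }) + "\n")
    if out_dir is not None:
        (out_dir / "benchmark.json").write_text(json.dumps(results, indent=1))
    return results
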