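"""Reading and writing feature tables, pseudo-image sets and run configs.

Tables are delimited text (CSV/TSV) with a header row and one binary label
column; everything else must be numeric.  Images are written either as
8-bit grayscale PNGs (for visual inspection) or as a lossless ``.npz``
bundle (for exact round-trips), always accompanied by a JSON manifest
mapping files to sample ids and labels.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "TabularDataset", "PseudoImageSet", "RunConfig",
    "load_table", "save_table", "save_images", "load_images",
]


@dataclass
class TabularDataset:
    """A samples x features numeric matrix with binary labels.

    Parameters
    ----------
    X : ndarray of shape (n_samples, p_features)
        Feature values, column order as in the source file.
    y : ndarray of shape (n_samples,)
        Binary labels in {0, 1}.
    feature_names : list of str
        Unique names, one per column of ``X``.
    sample_ids : list of str
        One id per row of ``X``.
    label_mapping : dict, optional
        Original label value -> {0, 1} assignment used at load time.
    metadata : dict, optional
        Free-form provenance (e.g. realized simulation parameters).
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    label_mapping: dict[Any, int] = field(default_factory=dict)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        n, p = self.X.shape
        if self.y.shape != (n,):
            raise ValueError(f"y has length {self.y.shape}, expected ({n},)")
        uniq = np.unique(self.y)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError("labels must be a subset of {0, 1}")
        self.y = self.y.astype(int)
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must equal p_features")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature_names must be unique")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must equal n_samples")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def p_features(self) -> int:
        return self.X.shape[1]


@dataclass
class PseudoImageSet:
    """A stack of grayscale pseudo-images, one per sample.

    ``images`` has shape (n_samples, Nr, Nc) with intensities in [0, 1].
    """

    images: np.ndarray
    y: np.ndarray
    layout_id: str = ""
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.images.ndim != 3:
            raise ValueError("images must have shape (n, Nr, Nc)")
        if self.images.shape[0] != self.y.shape[0]:
            raise ValueError("one image per sample required")
        lo, hi = self.images.min(initial=0.0), self.images.max(initial=0.0)
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.images.shape[0])]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.images.shape[1], self.images.shape[2]


@dataclass
class RunConfig:
    """Settings for a simulate -> convert -> evaluate run."""

    metric_name: str = "ED"
    grid_shape: tuple[int, int] = (50, 50)
    max_steps: int = 3000
    stall_limit: int = 200
    geodesic_k: int = 10
    folds: int = 10
    repeats: int = 1
    seed: int = 0
    cnn: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        from .distances import METRICS

        if self.metric_name not in METRICS:
            raise ValueError(f"metric_name must be one of {METRICS}")
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


def _sniff_delimiter(path: Path) -> str:
    sample = path.open().readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def load_table(
    path: str | Path,
    label_column: str,
    delimiter: str | None = None,
    impute: bool = False,
    zscore: bool = False,
) -> TabularDataset:
    """Load a delimited text table into a :class:`TabularDataset`.

    The label column may hold any two distinct values; they are mapped to
    {0, 1} in lexical order of their string form and the mapping is logged.
    Missing feature values are rejected unless ``impute`` is set, in which
    case they are replaced by the per-feature median.  ``zscore``
    optionally standardizes every feature column after loading (off by
    default: distances are computed on raw values).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter)
    if label_column not in df.columns:
        raise KeyError(f"label column {label_column!r} not found in {path.name}")
    labels_raw = df[label_column]
    feats = df.drop(columns=[label_column])

    levels = sorted(labels_raw.unique(), key=str)
    if len(levels) > 2:
        raise ValueError(f"label column has {len(levels)} levels; at most 2 allowed")
    mapping = {lv: i for i, lv in enumerate(levels)}
    logger.info("label mapping: %s", mapping)
    y = labels_raw.map(mapping).to_numpy()

    vals = feats.apply(pd.to_numeric, errors="coerce")
    bad = vals.isna() & ~feats.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric feature cell at row {r} column {feats.columns[c]!r}"
        )
    if vals.isna().any().any():
        if not impute:
            r, c = np.argwhere(vals.isna().to_numpy())[0]
            raise ValueError(
                f"missing value at row {r} column {vals.columns[c]!r}; "
                "pass impute=True for per-feature median imputation"
            )
        vals = vals.fillna(vals.median())
    X = vals.to_numpy(dtype=float)
    if zscore:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return TabularDataset(
        X=X,
        y=y,
        feature_names=[str(c) for c in vals.columns],
        sample_ids=[str(i) for i in df.index],
        label_mapping=mapping,
    )


def save_table(ds: TabularDataset, path: str | Path, label_column: str = "label") -> None:
    """Write a dataset back to CSV (features in column order, label last)."""
    df = pd.DataFrame(ds.X, columns=ds.feature_names)
    df[label_column] = ds.y
    df.to_csv(path, index=False)


def save_images(imgs: PseudoImageSet, out_dir: str | Path, format: str = "npz") -> Path:
    """Write a pseudo-image set to ``out_dir`` and return the manifest path.

    ``png8`` writes one 8-bit grayscale PNG per sample (intensity ``i``
    maps to ``round(255 * i)`` with round-half-up); ``npz`` writes a single
    lossless array bundle.  Both write ``manifest.json`` listing
    file / sample id / label.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    if format == "png8":
        # round-half-up, not banker's rounding
        quant = np.floor(imgs.images * 255.0 + 0.5).clip(0, 255).astype(np.uint8)
        for i, sid in enumerate(imgs.sample_ids):
            fname = f"{i:05d}_{sid}.png"
            Image.fromarray(quant[i], mode="L").save(out_dir / fname)
            entries.append({"file": fname, "sample_id": sid, "label": int(imgs.y[i])})
    elif format == "npz":
        fname = "images.npz"
        np.savez(
            out_dir / fname,
            images=imgs.images,
            y=imgs.y,
            sample_ids=np.array(imgs.sample_ids),
            layout_id=np.array(imgs.layout_id),
        )
        entries = [
            {"file": fname, "sample_id": sid, "label": int(lab)}
            for sid, lab in zip(imgs.sample_ids, imgs.y)
        ]
    else:
        raise ValueError("format must be 'png8' or 'npz'")
    manifest = out_dir / "manifest.json"
    manifest.write_text(
        json.dumps({"format": format, "layout_id": imgs.layout_id, "entries": entries}, indent=1)
    )
    return manifest


def load_images(path: str | Path) -> PseudoImageSet:
    """Load a pseudo-image set from an ``images.npz`` bundle."""
    path = Path(path)
    if path.is_dir():
        path = path / "images.npz"
    with np.load(path) as z:
        return PseudoImageSet(
            images=z["images"],
            y=z["y"],
            layout_id=str(z["layout_id"]),
            sample_ids=[str(s) for s in z["sample_ids"]],
        )
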