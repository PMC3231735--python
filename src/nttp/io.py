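"""Image and feature-table I/O plus the serialisable run configuration.

Coordinate convention used throughout the package: images are (row,
col) arrays, 0-based, with the row index increasing downward.  Inputs
are 8-bit PNG/PGM/TIFF rasters; colour images are collapsed to
luminance with Rec. 601 weights (0.299 R + 0.587 G + 0.114 B) and
16-bit images are rescaled to the [0, 255] range with a warning, since
the square-root noise band is calibrated for the 8-bit dynamic range.

Feature tables are CSV with one row per image: an ``image_id`` column,
a ``label`` column, then one column per feature entry whose header
encodes the layout triple ``segment:center:bin``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import LabeledDataset
from .core import FeatureVector

__all__ = [
    "RunConfig",
    "read_image",
    "write_image",
    "write_features",
    "read_features",
]

logger = logging.getLogger("nttp")

_REC601 = np.array([0.299, 0.587, 0.114])


def read_image(path) -> np.ndarray:
    """Load a raster as a float grayscale array in [0, 255].

    Raises
    ------
    ValueError
        If the file cannot be decoded or has an unsupported layout.
    """
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various backend errors
        raise ValueError(f"cannot decode image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ValueError(
                f"unsupported channel count {arr.shape[2]} in {path}"
            )
        arr = arr.astype(float) @ _REC601
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")
    arr = arr.astype(float)
    if arr.max(initial=0.0) > 255.0:
        warnings.warn(
            f"{path.name}: rescaling >8-bit data to [0, 255]; the noise band "
            "assumes the 8-bit dynamic range",
            stacklevel=2,
        )
        arr = arr * (255.0 / arr.max())
    return np.clip(arr, 0.0, 255.0)


def write_image(path, image: np.ndarray) -> None:
    """Write a [0, 255] array as an 8-bit grayscale raster."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(image), 0, 255).round().astype(np.uint8)
    iio.imwrite(Path(path), arr)


def _column_name(entry) -> str:
    seg, center, bin_ = entry
    return f"{seg}:{center}:{bin_}"


def _parse_column(name: str):
    seg, center, bin_ = name.rsplit(":", 2)
    return (seg, int(center), int(bin_))


def write_features(path, vectors, ids, labels) -> None:
    """Write feature vectors to CSV with a layout-encoding header."""
    vectors = list(vectors)
    if not vectors:
        raise ValueError("no feature vectors to write")
    layout = vectors[0].layout
    for v in vectors[1:]:
        if v.layout != layout:
            raise ValueError("inconsistent feature layouts")
    df = pd.DataFrame(
        np.vstack([v.values for v in vectors]),
        columns=[_column_name(e) for e in layout],
    )
    df.insert(0, "label", list(labels))
    df.insert(0, "image_id", list(ids))
    df.to_csv(path, index=False)


def read_features(path):
    """Read a feature CSV back into (LabeledDataset, image_ids, layout)."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"feature table {path} is empty")
    if list(df.columns[:2]) != ["image_id", "label"]:
        raise ValueError("feature CSV must start with image_id,label columns")
    feat_cols = df.columns[2:]
    if len(feat_cols) == 0:
        raise ValueError("feature CSV has no feature columns")
    try:
        layout = [_parse_column(c) for c in feat_cols]
    except Exception as exc:
        raise ValueError(f"malformed feature header: {exc}") from exc
    values = df[feat_cols].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("feature CSV contains missing or non-finite entries")
    data = LabeledDataset(values, df["label"].to_numpy())
    return data, df["image_id"].tolist(), layout


@dataclass
class RunConfig:
    """Everything that, with the input data, determines a run."""

    descriptor: str = "nttp"
    n: int = 8
    r: int = 2
    tau: float = 5.0
    R: float = 26.0
    band_mode: str = "adaptive"
    beta: float = 0.0
    alpha: float = 5.0
    scheme: str = "smc"
    metric: str = "chi2"
    folds: int = 10
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def log(self) -> None:
        logger.info("run config: %s", json.dumps(asdict(self), sort_keys=True))
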