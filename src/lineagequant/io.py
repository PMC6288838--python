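"""Reading and writing the pipeline's on-disk formats.

Images and label masks travel as 16-bit grayscale TIFF (single- or
multi-page, via tifffile); metadata and truth records as JSON; traces,
measurements and screen tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["write_image", "read_image", "write_labels", "read_labels",
           "write_json", "read_json"]

U16_MAX = np.iinfo(np.uint16).max


def write_image(path, image: np.ndarray) -> None:
    """Write a counts image (or stack) as 16-bit TIFF, clipping to range."""
    arr = np.clip(np.rint(np.asarray(image, float)), 0, U16_MAX).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_image(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_labels(path, labels: np.ndarray, legend: dict[int, str]) -> None:
    """Label TIFF plus a sidecar JSON legend mapping code -> name."""
    if np.max(labels) > U16_MAX:
        raise ValueError("too many labels for 16-bit TIFF")
    tifffile.imwrite(str(path), np.asarray(labels).astype(np.uint16))
    write_json(Path(str(path)).with_suffix(".json"),
               {str(k): v for k, v in legend.items()})


def read_labels(path) -> tuple[np.ndarray, dict[int, str]]:
    labels = tifffile.imread(str(path)).astype(np.int64)
    legend = {int(k): v for k, v in read_json(Path(str(path)).with_suffix(".json")).items()}
    return labels, legend


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
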