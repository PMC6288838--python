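"""Per-cell volumes (pL) from labeled 3D stacks.

Volumes are voxel counts times the voxel volume (1 pL = 1000 um^3);
voxel assignment is winner-take-all, so splitting a label conserves
volume exactly.  Segmentation of a membrane-marker stack is a seeded
watershed on the membrane intensity: cells are intensity basins walled
in by the bright membrane shell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.segmentation import find_boundaries, watershed

from ._util import round_half_up

__all__ = ["LabeledVolume", "volumes_from_labels", "segment_membrane_stack",
           "volume_ratio"]


@dataclass(frozen=True)
class LabeledVolume:
    """3D integer label array with voxel size and label -> cell-name map."""

    labels: np.ndarray
    voxel_size_um: tuple[float, float, float]        # (z, y, x)
    label_map: dict[int, str]

    def __post_init__(self):
        if np.min(self.labels) < 0:
            raise ValueError("labels must be >= 0 (0 = background)")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be > 0")

    @property
    def voxel_volume_pL(self) -> float:
        vz, vy, vx = self.voxel_size_um
        return vz * vy * vx / 1000.0


def volumes_from_labels(lv: LabeledVolume) -> dict[str, float]:
    """Map cell name -> volume in pL.  Labels with zero voxels are absent."""
    ids, counts = np.unique(lv.labels, return_counts=True)
    out = {}
    for i, n in zip(ids, counts):
        if i == 0:
            continue
        if int(i) not in lv.label_map:
            raise ValueError(f"label {int(i)} missing from the cell-name map")
        out[lv.label_map[int(i)]] = float(n) * lv.voxel_volume_pL
    if not out:
        raise ValueError("no nonzero labels")
    return out


def segment_membrane_stack(zstack: np.ndarray,
                           seeds: dict[str, tuple[int, int, int]],
                           voxel_size_um=(1.0, 0.5, 0.5)) -> LabeledVolume:
    """Seeded watershed on membrane intensity.

    ``seeds`` maps cell name -> (z, y, x) interior voxel.  An implicit
    background seed at the stack corners claims the exterior, so every
    cell label is bounded by the membrane ridge.  Two seeds falling in a
    single basin (no membrane ridge between them) are rejected.
    """
    zstack = np.asarray(zstack, dtype=float)
    if not seeds:
        raise ValueError("need at least one seed")
    markers = np.zeros(zstack.shape, dtype=np.int32)
    label_map: dict[int, str] = {}
    for i, (name, (z, y, x)) in enumerate(seeds.items(), start=1):
        if markers[z, y, x] != 0:
            raise ValueError(f"seeds {label_map[markers[z, y, x]]!r} and {name!r} "
                             "share a voxel")
        markers[z, y, x] = i
        label_map[i] = name
    bg_id = len(seeds) + 1
    for z in (0, -1):
        for y in (0, -1):
            for x in (0, -1):
                markers[z, y, x] = bg_id
    ws = watershed(zstack, markers)
    # basin-sharing check: a true cell-cell interface runs along the bright
    # membrane; a boundary through dark cytoplasm means two seeds shared a basin
    ridge_level = threshold_otsu(zstack)
    for a in range(1, bg_id):
        for b in range(a + 1, bg_id):
            touching = find_boundaries(ws == a, mode="outer") & (ws == b)
            if touching.any() and np.median(zstack[touching]) < ridge_level:
                raise ValueError(
                    f"seeds {label_map[a]!r} and {label_map[b]!r} lie in one basin "
                    "(no membrane ridge separates them)")
    ws[ws == bg_id] = 0
    return LabeledVolume(labels=ws.astype(np.uint16), voxel_size_um=tuple(voxel_size_um),
                         label_map=label_map)


def volume_ratio(v_germ: float, v_soma: float, decimals: int = 2) -> float:
    """Somatic/germline daughter volume ratio, rounded half-up."""
    if v_germ <= 0 or v_soma <= 0:
        raise ValueError("volumes must be > 0")
    return round_half_up(v_soma / v_germ, decimals)
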