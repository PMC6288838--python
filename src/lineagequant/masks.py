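"""Compartment masks: boolean label layers over one midplane image.

Masks are half-open rasters -- each pixel belongs to exactly one
compartment: the extracellular bath, or exactly one cell, within which it
is either cytoplasm or nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CellMasks", "CompartmentMasks"]


@dataclass(frozen=True)
class CellMasks:
    total: np.ndarray
    cytoplasm: np.ndarray
    nucleus: np.ndarray

    def __post_init__(self):
        if np.logical_and(self.cytoplasm, self.nucleus).any():
            raise ValueError("cytoplasm and nucleus masks overlap")
        if not np.array_equal(np.logical_or(self.cytoplasm, self.nucleus), self.total):
            raise ValueError("cytoplasm | nucleus must equal the whole-cell mask")


@dataclass(frozen=True)
class CompartmentMasks:
    """Embryo / bath / per-cell compartment layers for one image."""

    embryo: np.ndarray
    bath: np.ndarray
    cells: dict[str, CellMasks]
    pixel_size_um: float
    camera_background_region: np.ndarray | None = None

    def __post_init__(self):
        if np.logical_and(self.embryo, self.bath).any():
            raise ValueError("bath and embryo masks overlap")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.embryo.shape

    def cell_names(self) -> list[str]:
        return list(self.cells)

    # -- label-image round trip (for 16-bit label TIFF + JSON legend) ----

    def to_label_image(self) -> tuple[np.ndarray, dict[int, str]]:
        """Encode as an integer label image plus a code -> name legend.

        Code 0 is the bath; odd/even codes pair cytoplasm and nucleus of
        each cell.  Pixels inside the embryo outline but in no cell (there
        normally are none) share the bath code.
        """
        label = np.zeros(self.shape, dtype=np.uint16)
        legend: dict[int, str] = {0: "bath"}
        code = 1
        for name, cm in self.cells.items():
            label[cm.cytoplasm] = code
            legend[code] = f"{name}/cytoplasm"
            label[cm.nucleus] = code + 1
            legend[code + 1] = f"{name}/nucleus"
            code += 2
        return label, legend

    @classmethod
    def from_label_image(cls, label: np.ndarray, legend: dict[int, str],
                         pixel_size_um: float) -> "CompartmentMasks":
        legend = {int(k): v for k, v in legend.items()}
        layers: dict[str, dict[str, np.ndarray]] = {}
        bath = np.zeros(label.shape, dtype=bool)
        for code, name in legend.items():
            m = label == code
            if name == "bath":
                bath |= m
                continue
            cell, _, comp = name.partition("/")
            layers.setdefault(cell, {})[comp or "cytoplasm"] = m
        cells = {}
        for cell, comps in layers.items():
            cyt = comps.get("cytoplasm", np.zeros(label.shape, bool))
            nuc = comps.get("nucleus", np.zeros(label.shape, bool))
            cells[cell] = CellMasks(total=cyt | nuc, cytoplasm=cyt, nucleus=nuc)
        embryo = np.zeros(label.shape, dtype=bool)
        for cm in cells.values():
            embryo |= cm.total
        return cls(embryo=embryo, bath=bath, cells=cells, pixel_size_um=pixel_size_um)
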