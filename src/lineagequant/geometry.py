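"""Embryo geometry: the elliptical midplane, cell subregions and nuclei.

The embryo midplane is an ellipse whose major axis is the anteroposterior
(AP) axis, anterior at AP coordinate 0 and posterior at 1.  Cells are
AP-coordinate intervals of the ellipse, which guarantees that cells tile
the embryo without overlap; nuclei are small ellipses inside their cells.
For volume work (a separate acquisition in practice) cells are 3D
ellipsoids, handled in :mod:`lineagequant.synthetic`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .masks import CellMasks, CompartmentMasks

__all__ = ["EmbryoGeometry", "Ellipsoid"]


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned 3D ellipsoid, centre and semi-axes in micrometres (z, y, x)."""

    center_um: tuple[float, float, float]
    radii_um: tuple[float, float, float]

    def __post_init__(self):
        if any(r <= 0 for r in self.radii_um):
            raise ValueError("ellipsoid radii must be positive")

    @property
    def volume_pL(self) -> float:
        """Analytic volume; 1 pL = 1000 um^3."""
        a, b, c = self.radii_um
        return 4.0 / 3.0 * math.pi * a * b * c / 1000.0


@dataclass(frozen=True)
class EmbryoGeometry:
    """Midplane geometry of one embryo.

    ``cell_spans`` maps cell name -> (lo, hi) fractions of the AP extent;
    spans must be disjoint and cover (0, 1).  ``nuclei`` maps cell name ->
    ((cy, cx), (ry, rx)) nucleus ellipse in pixels.
    """

    shape: tuple[int, int]
    center: tuple[float, float]          # (y, x) pixels
    axes: tuple[float, float]            # (semi-major along AP, semi-minor) pixels
    orientation: float                   # AP axis angle, radians; 0 = +x is posterior
    pixel_size_um: float
    cell_spans: dict[str, tuple[float, float]]
    nuclei: dict[str, tuple[tuple[float, float], tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        spans = sorted(self.cell_spans.values())
        for (l1, h1), (l2, h2) in zip(spans, spans[1:]):
            if h1 > l2 + 1e-12:
                raise ValueError("cell spans overlap")
        for name in self.nuclei:
            if name not in self.cell_spans:
                raise ValueError(f"nucleus for unknown cell {name!r}")

    # -- coordinate fields ----------------------------------------------

    def _grids(self):
        ny, nx = self.shape
        y, x = np.mgrid[0:ny, 0:nx]
        cy, cx = self.center
        ca, sa = math.cos(self.orientation), math.sin(self.orientation)
        u = (x - cx) * ca + (y - cy) * sa          # along AP, pixels
        v = -(x - cx) * sa + (y - cy) * ca         # across AP, pixels
        return u, v

    def embryo_mask(self) -> np.ndarray:
        a, b = self.axes
        u, v = self._grids()
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def bath_mask(self) -> np.ndarray:
        return ~self.embryo_mask()

    def ap_coordinate(self) -> np.ndarray:
        """Normalized AP coordinate in [0, 1] (anterior 0, posterior 1)."""
        a, _ = self.axes
        u, _ = self._grids()
        return (u + a) / (2 * a)

    def cell_mask(self, name: str) -> np.ndarray:
        if name not in self.cell_spans:
            raise KeyError(f"unknown cell {name!r}")
        lo, hi = self.cell_spans[name]
        ap = self.ap_coordinate()
        m = self.embryo_mask() & (ap >= lo) & (ap < hi)
        # the posterior-most cell owns the closed boundary ap == 1
        if hi >= 1.0 - 1e-12:
            m |= self.embryo_mask() & (ap >= lo)
        return m

    def nucleus_mask(self, name: str) -> np.ndarray:
        if name not in self.nuclei:
            return np.zeros(self.shape, dtype=bool)
        (cy, cx), (ry, rx) = self.nuclei[name]
        ny, nx = self.shape
        y, x = np.mgrid[0:ny, 0:nx]
        m = ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0
        cell = self.cell_mask(name)
        if m.any() and not np.all(cell[m]):
            raise ValueError(f"nucleus of {name!r} extends outside its cell")
        return m

    def masks(self) -> CompartmentMasks:
        embryo = self.embryo_mask()
        cells = {}
        for name in self.cell_spans:
            total = self.cell_mask(name)
            nuc = self.nucleus_mask(name)
            cells[name] = CellMasks(total=total, cytoplasm=total & ~nuc, nucleus=nuc)
        return CompartmentMasks(embryo=embryo, bath=~embryo, cells=cells,
                                pixel_size_um=self.pixel_size_um)

    # -- stage constructors ---------------------------------------------

    @classmethod
    def blank(cls, shape=(128, 192), pixel_size_um: float = 0.3,
              axes: tuple[float, float] = (80.0, 48.0),
              orientation: float = 0.0) -> "EmbryoGeometry":
        """Embryo outline with no cell subdivisions yet."""
        ny, nx = shape
        return cls(shape=shape, center=((ny - 1) / 2, (nx - 1) / 2), axes=axes,
                   orientation=orientation, pixel_size_um=pixel_size_um,
                   cell_spans={}, nuclei={})

    def with_cells(self, spans: dict[str, tuple[float, float]],
                   nuclei: dict | None = None,
                   default_nuclei: bool = False,
                   nucleus_radius_px: float = 8.0) -> "EmbryoGeometry":
        """Return a copy with the given AP spans (and optional nuclei)."""
        nuc = dict(nuclei or {})
        if default_nuclei:
            cy, cx = self.center
            a, _ = self.axes
            ca, sa = math.cos(self.orientation), math.sin(self.orientation)
            for name, (lo, hi) in spans.items():
                mid = (lo + hi) / 2
                u = (2 * mid - 1) * a
                nuc.setdefault(name, ((cy + u * sa, cx + u * ca),
                                      (nucleus_radius_px, nucleus_radius_px)))
        return replace(self, cell_spans=dict(spans), nuclei=nuc)

    @classmethod
    def one_cell(cls, nuclei: bool = False, **kw) -> "EmbryoGeometry":
        return cls.blank(**kw).with_cells({"P0": (0.0, 1.0)}, default_nuclei=nuclei)

    @classmethod
    def two_cell(cls, ab_fraction: float = 14.7 / 24.8, nuclei: bool = True,
                 **kw) -> "EmbryoGeometry":
        """AB anterior, P1 posterior; split at the volume-proportional point."""
        return cls.blank(**kw).with_cells(
            {"AB": (0.0, ab_fraction), "P1": (ab_fraction, 1.0)}, default_nuclei=nuclei)

    @classmethod
    def four_cell(cls, nuclei: bool = True, **kw) -> "EmbryoGeometry":
        s = 14.7 / 24.8
        ems = s + (1 - s) * 6.1 / 10.3
        return cls.blank(**kw).with_cells(
            {"ABa": (0.0, s / 2), "ABp": (s / 2, s),
             "EMS": (s, ems), "P2": (ems, 1.0)}, default_nuclei=nuclei)
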