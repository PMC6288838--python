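"""Synthetic microscopy scenes with known ground truth.

Everything the analysis modules consume can be generated here: bath
calibration images (embryo in a uniform extracellular GFP bath), lineage
time-lapses with asymmetric divisions, photobleaching and lineage-
restricted synthesis, membrane-marker z-stacks for volumetrics, and
two-stage RNAi-screen tables.  All randomness flows from a single seed
through numpy's splittable SeedSequence.

The default lineage parameters encode the measured biology of the early
C. elegans embryo: a 92 nM zygote concentration at nuclear envelope
breakdown, segregation fractions of 0.58 (P0 -> P1) and 0.57 (P1 -> P2),
blastomere volumes 14.7/10.1 pL (AB/P1) and 6.1/4.2 pL (EMS/P2),
germline-restricted synthesis, and ZIF-1-dependent degradation in the
anterior somatic cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import rng_from, spawn_rngs
from .geometry import EmbryoGeometry, Ellipsoid
from .masks import CompartmentMasks
from .optics import OpticsModel

__all__ = [
    "CalibrationScene", "make_bath_image", "make_calibration_scene",
    "DivisionEvent", "BleachEvent", "LineageParams", "default_lineage_params",
    "Timelapse", "make_lineage_timelapse", "simulate_traces",
    "bleach_for_target", "posterior_circle_center",
    "make_membrane_stack", "seed_points",
    "make_screen_dataset", "make_two_stage_screen",
]


# ---------------------------------------------------------------------------
# calibration scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationScene:
    """A rendered bath-calibration image plus its ground truth."""

    image: np.ndarray
    masks: CompartmentMasks
    bath_nM: float
    true_conc_nM: dict[str, float]       # "cell/compartment" -> nM
    optics: OpticsModel


def make_bath_image(optics: OpticsModel, bath_nM: float, seed=None,
                    noise: bool = True) -> np.ndarray:
    """Image of a uniform fluorophore solution (no embryo in the frame)."""
    if bath_nM < 0:
        raise ValueError("bath_nM must be >= 0")
    conc = np.full(optics.shape, float(bath_nM))
    return optics.render(conc, rng=seed, noise=noise)


def _expand_compartment_conc(geometry: EmbryoGeometry,
                             true_conc: dict[str, float]) -> dict[str, float]:
    """Expand {"P1": 150, "P1/nucleus": 500} to per-compartment values."""
    out: dict[str, float] = {}
    for key in true_conc:
        cell = key.split("/")[0]
        if cell not in geometry.cell_spans:
            raise ValueError(f"unknown compartment {key!r}: no cell named {cell!r}")
    for name in geometry.cell_spans:
        base = true_conc.get(name, 0.0)
        out[f"{name}/cytoplasm"] = true_conc.get(f"{name}/cytoplasm", base)
        out[f"{name}/nucleus"] = true_conc.get(f"{name}/nucleus", base)
    return out


def make_calibration_scene(geometry: EmbryoGeometry, optics: OpticsModel,
                           bath_nM: float, true_conc_by_compartment: dict[str, float],
                           seed=None, noise: bool = True) -> CalibrationScene:
    """Render an embryo in a fluorophore bath with known compartment concentrations.

    ``true_conc_by_compartment`` keys are cell names (whole cell) or
    "cell/cytoplasm", "cell/nucleus" overrides, in nM.  Autofluorescence
    (from ``optics``) is added everywhere inside the embryo.
    """
    if bath_nM < 0:
        raise ValueError("bath_nM must be >= 0")
    if geometry.shape != optics.shape:
        raise ValueError("geometry and optics frame shapes differ")
    conc = _expand_compartment_conc(geometry, true_conc_by_compartment)
    masks = geometry.masks()
    conc_map = np.zeros(geometry.shape)
    conc_map[masks.bath] = bath_nM
    for name, cm in masks.cells.items():
        conc_map[cm.cytoplasm] = conc[f"{name}/cytoplasm"]
        conc_map[cm.nucleus] = conc[f"{name}/nucleus"]
    conc_map[masks.embryo] += optics.autofluorescence_nM_equiv
    image = optics.render(conc_map, rng=seed, noise=noise)
    truth = dict(conc)
    truth["bath"] = bath_nM
    return CalibrationScene(image=image, masks=masks, bath_nM=bath_nM,
                           true_conc_nM=truth, optics=optics)


# ---------------------------------------------------------------------------
# lineage time-lapse
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DivisionEvent:
    """Instantaneous division: the posterior daughter receives ``fraction``
    of the mother's amount.  In the P-lineage divisions the posterior
    daughter is the germline daughter; for the symmetric AB division the
    labels are purely positional."""

    time_s: float
    mother: str
    germ_daughter: str       # posterior
    soma_daughter: str       # anterior
    fraction: float          # amount fraction inherited by the posterior daughter

    def __post_init__(self):
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("segregation fraction must be in (0, 1)")


@dataclass(frozen=True)
class BleachEvent:
    """Photobleach of a circular region.

    Each repetition multiplies the matured (fluorescent) amount inside the
    circle by ``survival`` and then lets the cell mix; repeated short
    pulses therefore deplete the whole cell far below the single-pulse
    floor, as in the standard 25-repetition protocol.
    """

    time_s: float
    center_px: tuple[float, float]       # (y, x)
    diameter_um: float
    survival: float
    repetitions: int = 1

    def __post_init__(self):
        if not 0.0 <= self.survival <= 1.0:
            raise ValueError("survival must be in [0, 1]")
        if self.diameter_um <= 0 or self.repetitions < 1:
            raise ValueError("diameter must be > 0 and repetitions >= 1")


@dataclass(frozen=True)
class LineageParams:
    """Ground-truth kinetic parameters of a lineage simulation.

    Rates: ``k_syn`` in nM/s per cell (lineage-restricted translation),
    ``k_deg`` in 1/s per cell (nonzero only where ZIF-1 is active).
    Between events each cell obeys dC/dt = k_syn - k_deg * C; at a
    division the mother amount splits ``fraction`` : 1 - ``fraction``.
    """

    initial_concentration_nM: float = 92.0
    volumes_pL: dict[str, float] = field(default_factory=dict)
    divisions: tuple[DivisionEvent, ...] = ()
    k_syn: dict[str, float] = field(default_factory=dict)
    k_deg: dict[str, float] = field(default_factory=dict)
    maturation_delay_s: float = 0.0
    bleaches: tuple[BleachEvent, ...] = ()
    root_cell: str = "P0"

    def __post_init__(self):
        if self.initial_concentration_nM < 0 or self.maturation_delay_s < 0:
            raise ValueError("concentration and maturation delay must be >= 0")
        if any(r < 0 for r in list(self.k_syn.values()) + list(self.k_deg.values())):
            raise ValueError("rates must be >= 0")
        times = [d.time_s for d in self.divisions]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("division times must be strictly increasing")
        if any(v <= 0 for v in self.volumes_pL.values()):
            raise ValueError("volumes must be > 0")


#: measured blastomere volumes (pL); P0 is the sum of its daughters
DEFAULT_VOLUMES_PL = {
    "P0": 24.8, "AB": 14.7, "P1": 10.1,
    "ABa": 7.35, "ABp": 7.35, "EMS": 6.1, "P2": 4.2,
}


def default_lineage_params(k_syn_germline: float = 0.06,
                           k_deg_somatic: float = 0.003,
                           f1: float = 0.58, f2: float = 0.57,
                           t_div1: float = 900.0, t_div2: float = 1800.0,
                           t_div_ab: float = 1750.0,
                           bleaches: tuple[BleachEvent, ...] = (),
                           maturation_delay_s: float = 0.0,
                           c0_nM: float = 92.0) -> LineageParams:
    """The study conditions: P0 -> (AB, P1) -> (ABa/ABp, EMS/P2).

    Synthesis is restricted to the germline (P) cells at ``k_syn_germline``
    nM/s; degradation acts in ABa/ABp where ZIF-1 is active.  Division
    times are seconds after pronuclear meeting.
    """
    divisions = (
        DivisionEvent(t_div1, "P0", "P1", "AB", f1),
        DivisionEvent(t_div_ab, "AB", "ABp", "ABa", 0.5),
        DivisionEvent(t_div2, "P1", "P2", "EMS", f2),
    )
    return LineageParams(
        initial_concentration_nM=c0_nM,
        volumes_pL=dict(DEFAULT_VOLUMES_PL),
        divisions=divisions,
        k_syn={"P0": k_syn_germline, "P1": k_syn_germline, "P2": k_syn_germline},
        k_deg={"ABa": k_deg_somatic, "ABp": k_deg_somatic},
        maturation_delay_s=maturation_delay_s,
        bleaches=tuple(sorted(bleaches, key=lambda b: b.time_s)),
    )


class _Cell:
    __slots__ = ("name", "volume", "span", "a_fluor", "a_total", "dark", "hole")

    def __init__(self, name, volume, span, a_fluor, a_total):
        self.name = name
        self.volume = volume          # pL
        self.span = span              # AP (lo, hi)
        self.a_fluor = a_fluor        # matured amount, nM*pL
        self.a_total = a_total        # total amount (matured + dark)
        self.dark = []                # [(amount, mature_time_s), ...]
        self.hole = None              # (circle_mask, survival) pending render


@dataclass(frozen=True)
class Timelapse:
    """Simulated time-lapse: images (optional), per-frame masks, and truth."""

    times_s: np.ndarray
    stack: np.ndarray | None
    masks: list[CompartmentMasks]
    truth: pd.DataFrame                 # time_s, cell, true_conc_nM, fluor_conc_nM, ...
    params: LineageParams
    geometry: EmbryoGeometry


def _circle_mask(shape, center_px, radius_px):
    y, x = np.mgrid[0:shape[0], 0:shape[1]]
    cy, cx = center_px
    return (y - cy) ** 2 + (x - cx) ** 2 <= radius_px ** 2


def posterior_circle_center(geometry: EmbryoGeometry, ap_frac: float = 0.8):
    """Pixel coordinates of a point on the AP axis (posterior cytoplasm)."""
    cy, cx = geometry.center
    a, _ = geometry.axes
    u = (2 * ap_frac - 1) * a
    return (cy + u * math.sin(geometry.orientation),
            cx + u * math.cos(geometry.orientation))


class _LineageSim:
    """Event-driven well-mixed compartment simulation over the midplane."""

    def __init__(self, params: LineageParams, geometry: EmbryoGeometry,
                 mask_cache: dict | None = None):
        self.params = params
        self.geom = geometry
        if params.root_cell not in params.volumes_pL:
            raise ValueError(f"no volume for root cell {params.root_cell!r}")
        v0 = params.volumes_pL[params.root_cell]
        a0 = params.initial_concentration_nM * v0
        self.cells: dict[str, _Cell] = {
            params.root_cell: _Cell(params.root_cell, v0, (0.0, 1.0), a0, a0)}
        self.t = 0.0
        self._mask_cache = mask_cache if mask_cache is not None else {}

    # -- kinetics --------------------------------------------------------

    def _advance(self, dt: float):
        if dt <= 0:
            return
        p = self.params
        t1 = self.t + dt
        for c in self.cells.values():
            ks = p.k_syn.get(c.name, 0.0)
            kd = p.k_deg.get(c.name, 0.0)
            decay = math.exp(-kd * dt)
            c.a_fluor *= decay
            c.dark = [(a * decay, tm) for a, tm in c.dark]
            if kd > 0:
                synth = ks * c.volume * (1 - decay) / kd
            else:
                synth = ks * c.volume * dt
            if synth > 0:
                if p.maturation_delay_s == 0:
                    c.a_fluor += synth
                else:
                    c.dark.append((synth, self.t + dt / 2 + p.maturation_delay_s))
            # mature dark pool
            still_dark = []
            for a, tm in c.dark:
                if tm <= t1:
                    c.a_fluor += a
                else:
                    still_dark.append((a, tm))
            c.dark = still_dark
            c.a_total = c.a_fluor + sum(a for a, _ in c.dark)
        self.t = t1

    def _divide(self, ev: DivisionEvent):
        if ev.mother not in self.cells:
            raise ValueError(f"division of unknown/dead cell {ev.mother!r}")
        mom = self.cells.pop(ev.mother)
        vols = self.params.volumes_pL
        for d in (ev.germ_daughter, ev.soma_daughter):
            if d not in vols:
                raise ValueError(f"no volume for daughter {d!r}")
        lo, hi = mom.span
        vg, vs = vols[ev.germ_daughter], vols[ev.soma_daughter]
        cut = lo + (hi - lo) * vs / (vs + vg)      # anterior (somatic) part first
        f = ev.fraction
        for name, span, share in ((ev.soma_daughter, (lo, cut), 1 - f),
                                  (ev.germ_daughter, (cut, hi), f)):
            cell = _Cell(name, vols[name], span, mom.a_fluor * share,
                         mom.a_total * share)
            cell.dark = [(a * share, tm) for a, tm in mom.dark]
            self.cells[name] = cell

    def _bleach(self, ev: BleachEvent):
        r_px = ev.diameter_um / 2 / self.geom.pixel_size_um
        circle = _circle_mask(self.geom.shape, ev.center_px, r_px)
        embryo = self.geom.embryo_mask()
        if not circle.any() or not np.all(embryo[circle]):
            raise ValueError("bleach circle lies (partly) outside the embryo")
        geom = self._stage_geometry()
        for c in self.cells.values():
            cell_mask = geom.cell_mask(c.name)
            n_cell = cell_mask.sum()
            n_in = (cell_mask & circle).sum()
            if n_in == 0:
                continue
            a_frac = n_in / n_cell
            for _ in range(ev.repetitions):
                c.a_fluor *= 1 - a_frac * (1 - ev.survival)
            c.a_total = c.a_fluor + sum(a for a, _ in c.dark)
            if ev.repetitions == 1:
                c.hole = (cell_mask & circle, ev.survival, a_frac)

    # -- geometry / rendering -------------------------------------------

    def _stage_geometry(self) -> EmbryoGeometry:
        key = tuple(sorted(self.cells))
        spans = {c.name: c.span for c in self.cells.values()}
        return self.geom.with_cells(spans)

    def _stage_masks(self) -> CompartmentMasks:
        key = tuple(sorted((c.name, c.span) for c in self.cells.values()))
        if key not in self._mask_cache:
            self._mask_cache[key] = self._stage_geometry().masks()
        return self._mask_cache[key]

    def conc_map(self, masks: CompartmentMasks) -> np.ndarray:
        out = np.zeros(self.geom.shape)
        for c in self.cells.values():
            conc = c.a_fluor / c.volume
            m = masks.cells[c.name].total
            if c.hole is not None:
                circle, s, a_frac = c.hole
                conc_out = c.a_fluor / (c.volume * (1 - a_frac * (1 - s)))
                out[m] = conc_out
                out[circle] = s * conc_out
                c.hole = None
            else:
                out[m] = conc
        return out


def make_lineage_timelapse(params: LineageParams, optics: OpticsModel,
                           interval_s: float, duration_s: float,
                           geometry: EmbryoGeometry | None = None,
                           seed=None, noise: bool = True,
                           render: bool = True,
                           mask_cache: dict | None = None) -> Timelapse:
    """Simulate and (optionally) render a lineage time-lapse.

    Frames are taken every ``interval_s`` from t=0 (pronuclear meeting) to
    ``duration_s``.  The truth table records, per frame and live cell, the
    total and matured (fluorescent) concentrations, the cell volume and
    the total amount.
    """
    if interval_s <= 0:
        raise ValueError("interval_s must be > 0")
    geometry = geometry or EmbryoGeometry.blank()
    if render and geometry.shape != optics.shape:
        raise ValueError("geometry and optics frame shapes differ")
    rng = rng_from(seed)
    sim = _LineageSim(params, geometry, mask_cache=mask_cache)
    events = sorted([("div", d.time_s, d) for d in params.divisions]
                    + [("bleach", b.time_s, b) for b in params.bleaches],
                    key=lambda e: e[1])
    times = np.arange(0.0, duration_s + 1e-9, interval_s)
    frames, mask_list, rows = [], [], []
    ei = 0
    for t in times:
        while ei < len(events) and events[ei][1] <= t:
            kind, te, ev = events[ei]
            sim._advance(te - sim.t)
            sim._divide(ev) if kind == "div" else sim._bleach(ev)
            ei += 1
        sim._advance(t - sim.t)
        masks = sim._stage_masks()
        mask_list.append(masks)
        if render:
            cmap = sim.conc_map(masks)
            cmap[masks.embryo] += optics.autofluorescence_nM_equiv
            frames.append(optics.render(cmap, rng=rng, noise=noise))
        else:
            for c in sim.cells.values():
                c.hole = None
        for c in sim.cells.values():
            rows.append((t, c.name, c.a_total / c.volume, c.a_fluor / c.volume,
                         c.volume, c.a_total, c.a_fluor))
    truth = pd.DataFrame(rows, columns=["time_s", "cell", "true_conc_nM",
                                        "fluor_conc_nM", "volume_pL",
                                        "amount", "fluor_amount"])
    stack = np.stack(frames) if render else None
    return Timelapse(times_s=times, stack=stack, masks=mask_list, truth=truth,
                     params=params, geometry=geometry)


def bleach_for_target(geometry: EmbryoGeometry,
                      target_fraction: float, time_s: float,
                      diameter_um: float = 8.0, repetitions: int = 25,
                      ap_frac: float = 0.8) -> BleachEvent:
    """Bleach event whose net whole-cell survival equals ``target_fraction``.

    Solves (1 - a (1 - s))^n = target for the per-pulse survival s, where
    ``a`` is the circle/cell area overlap fraction at the event time (the
    cell is assumed to be the root cell, i.e. the zygote).
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must be in (0, 1)")
    center = posterior_circle_center(geometry, ap_frac)
    r_px = diameter_um / 2 / geometry.pixel_size_um
    circle = _circle_mask(geometry.shape, center, r_px)
    cell = geometry.embryo_mask()
    a = (circle & cell).sum() / cell.sum()
    s = 1 - (1 - target_fraction ** (1.0 / repetitions)) / a
    if s < 0:
        raise ValueError("target unreachable: increase repetitions or circle size")
    return BleachEvent(time_s=time_s, center_px=center, diameter_um=diameter_um,
                       survival=s, repetitions=repetitions)


def simulate_traces(params: LineageParams, optics: OpticsModel,
                    interval_s: float, duration_s: float,
                    geometry: EmbryoGeometry | None = None,
                    seed=None, noise: bool = True,
                    mask_cache: dict | None = None,
                    return_timelapse: bool = False):
    """Fast path: per-cell background-corrected mean intensities without
    rendering images.

    The measured mean over a cell of N pixels has expectation
    photons_per_nM * (fluor_conc + autofluorescence) and standard error
    sqrt((photons_per_nM * conc + read_sd^2) / N) under the flat-field
    camera model; the Gaussian approximation to the Poisson mean is
    excellent at these counts.  Columns: time_s, cell, intensity (bg-
    corrected counts) plus the truth columns.
    """
    geometry = geometry or EmbryoGeometry.blank()
    tl = make_lineage_timelapse(params, optics, interval_s, duration_s,
                                geometry=geometry, seed=None, noise=False,
                                render=False, mask_cache=mask_cache)
    rng = rng_from(seed)
    # pixel counts per cell per stage
    npix: dict[str, int] = {}
    for masks in tl.masks:
        for name, cm in masks.cells.items():
            npix.setdefault(name, int(cm.total.sum()))
    df = tl.truth.copy()
    conc_vis = df["fluor_conc_nM"] + optics.autofluorescence_nM_equiv
    mean_counts = optics.photons_per_nM * conc_vis
    if noise:
        n = df["cell"].map(npix).to_numpy(float)
        var = (optics.photons_per_nM * conc_vis + optics.read_noise_sd ** 2) / n
        mean_counts = mean_counts + rng.normal(0.0, np.sqrt(var))
    df["intensity"] = mean_counts
    return (df, tl) if return_timelapse else df


# ---------------------------------------------------------------------------
# membrane z-stacks (for volumetrics)
# ---------------------------------------------------------------------------

def seed_points(cells: dict[str, Ellipsoid], voxel_size_um, origin_um=(0.0, 0.0, 0.0)):
    """Voxel indices of each ellipsoid centre (watershed seeds)."""
    vz, vy, vx = voxel_size_um
    return {name: (int(round((e.center_um[0] - origin_um[0]) / vz)),
                   int(round((e.center_um[1] - origin_um[1]) / vy)),
                   int(round((e.center_um[2] - origin_um[2]) / vx)))
            for name, e in cells.items()}


@dataclass(frozen=True)
class MembraneStack:
    """Rendered membrane-marker z-stack with its ground truth."""

    zstack: np.ndarray
    labels: "LabeledVolume"
    true_volumes_pL: dict[str, float]
    origin_um: tuple[float, float, float]
    cells: dict[str, Ellipsoid]

    def seeds(self) -> dict[str, tuple[int, int, int]]:
        return seed_points(self.cells, self.labels.voxel_size_um, self.origin_um)


def make_membrane_stack(cells: dict[str, Ellipsoid], voxel_size_um,
                        optics: OpticsModel | None = None, seed=None,
                        noise: bool = True, margin_um: float = 3.0,
                        membrane_nM: float = 400.0, interior_nM: float = 20.0,
                        shell_width: float = 0.08) -> MembraneStack:
    """Render a membrane-marker z-stack of non-overlapping cell ellipsoids.

    The returned object carries the rendered stack, the ground-truth
    `LabeledVolume` (voxel -> cell, 0 = background), the analytic
    ellipsoid volumes in pL, and the stack origin in micrometres.  The
    membrane marker is bright in a thin shell around each cell surface.
    """
    if any(v <= 0 for v in voxel_size_um):
        raise ValueError("voxel sizes must be > 0")
    if not cells:
        raise ValueError("need at least one cell")
    vz, vy, vx = (float(v) for v in voxel_size_um)
    los = np.array([[e.center_um[i] - e.radii_um[i] for i in range(3)]
                    for e in cells.values()])
    his = np.array([[e.center_um[i] + e.radii_um[i] for i in range(3)]
                    for e in cells.values()])
    origin = los.min(axis=0) - margin_um
    top = his.max(axis=0) + margin_um
    shape = tuple(int(np.ceil((top[i] - origin[i]) / v)) + 1
                  for i, v in enumerate((vz, vy, vx)))
    zz = origin[0] + np.arange(shape[0]) * vz
    yy = origin[1] + np.arange(shape[1]) * vy
    xx = origin[2] + np.arange(shape[2]) * vx
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")

    label = np.zeros(shape, dtype=np.uint16)
    membrane = np.zeros(shape)
    label_map: dict[int, str] = {}
    true_volumes = {}
    for i, (name, e) in enumerate(cells.items(), start=1):
        cz, cy, cx = e.center_um
        rz, ry, rx = e.radii_um
        q = ((Z - cz) / rz) ** 2 + ((Y - cy) / ry) ** 2 + ((X - cx) / rx) ** 2
        inside = q <= 1.0
        if np.any(label[inside] != 0):
            raise ValueError("ellipsoids overlap")
        label[inside] = i
        label_map[i] = name
        membrane += np.exp(-((np.sqrt(q) - 1.0) / shell_width) ** 2)
        true_volumes[name] = e.volume_pL

    optics = optics or OpticsModel.default(shape=(8, 8)).flat()
    expected = optics.photons_per_nM * (membrane * membrane_nM
                                        + (label > 0) * interior_nM)
    if noise:
        rng = rng_from(seed)
        zstack = (rng.poisson(expected).astype(float) + optics.camera_offset
                  + rng.normal(0, optics.read_noise_sd, size=shape))
    else:
        zstack = expected + optics.camera_offset
    from .volumetrics import LabeledVolume

    lv = LabeledVolume(labels=label, voxel_size_um=(vz, vy, vx),
                       label_map=label_map)
    return MembraneStack(zstack=zstack, labels=lv, true_volumes_pL=true_volumes,
                         origin_um=tuple(origin), cells=dict(cells))


# ---------------------------------------------------------------------------
# RNAi screen datasets
# ---------------------------------------------------------------------------

def make_screen_dataset(n_clones: int, embryos_per_clone, control_mean: float,
                        effect_sizes: dict[str, float] | None = None,
                        noise_cv: float = 0.15, seed=None,
                        camera_bg: float = 100.0, stage: int = 1,
                        control_clone: str = "control"):
    """Per-embryo germline-blastomere (P2) mean intensities for an RNAi screen.

    Each embryo of a clone with multiplier m draws its background-free
    signal from Normal(m * control_mean, noise_cv * m * control_mean); the
    recorded value adds the camera background.  Clones with multiplier 1
    (the default, and always the control clone) are true nulls.

    ``embryos_per_clone`` may be an int (single stage) or a {stage: n}
    mapping, in which case rows for every stage are generated.
    Returns a `lineagequant.screen.ScreenTable` whose data is tidy:
    clone, stage, embryo, p2_mean, camera_bg.
    """
    from .screen import ScreenTable
    effect_sizes = effect_sizes or {}
    if any(m < 0 for m in effect_sizes.values()):
        raise ValueError("effect-size multipliers must be >= 0")
    if isinstance(embryos_per_clone, dict):
        stage_n = {int(s): int(n) for s, n in embryos_per_clone.items()}
    else:
        stage_n = {stage: int(embryos_per_clone)}
    if any(n < 2 for n in stage_n.values()):
        raise ValueError("need at least 2 embryos per clone")
    rng = rng_from(seed)
    clones = [control_clone] + [f"clone_{i:03d}" for i in range(n_clones)]
    rows = []
    for st, n in sorted(stage_n.items()):
        for clone in clones:
            m = 1.0 if clone == control_clone else effect_sizes.get(clone, 1.0)
            mu = m * control_mean
            vals = rng.normal(mu, noise_cv * mu, size=n) if mu > 0 else np.zeros(n)
            for j, v in enumerate(vals):
                rows.append((clone, st, f"{clone}_s{st}_e{j}", v + camera_bg, camera_bg))
    df = pd.DataFrame(rows, columns=["clone", "stage", "embryo", "p2_mean",
                                     "camera_bg"])
    return ScreenTable(data=df, control_clone=control_clone)


def make_two_stage_screen(n_clones: int, n_stage1: int, n_stage2: int,
                          control_mean: float,
                          effect_sizes: dict[str, float] | None = None,
                          noise_cv: float = 0.15, seed=None,
                          **kw):
    """Convenience wrapper generating both screen stages at once."""
    return make_screen_dataset(n_clones, {1: n_stage1, 2: n_stage2},
                               control_mean, effect_sizes, noise_cv, seed, **kw)
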