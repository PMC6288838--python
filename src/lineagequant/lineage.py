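"""Mass-balance model of asymmetric protein partitioning in the P lineage.

At each asymmetric division a mother cell's protein amount A splits
between the germline daughter (fraction f) and the somatic daughter
(1 - f).  From the measured daughter volumes and relative concentrations,

    f = c_g v_g / (c_g v_g + c_s v_s),

and the concentration attributable purely to inherited maternal protein
after a chain of divisions is

    C_pred = C0 * phi * prod_i f_i,

where C0 is the zygote concentration and phi the zygote-to-final-cell
volume fold decrease.  Comparing C_pred with the observed concentration
decomposes the enrichment into inheritance and new synthesis:
synthesized fraction = 1 - C_pred / C_obs.

`PartitioningModel` packages this arithmetic as a fitted model over a
table of division measurements; `fit_partitioning` extracts those
measurements from time-lapse traces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import round_half_up

__all__ = [
    "DivisionMeasurement", "InheritancePrediction",
    "segregation_fraction", "predict_inherited_concentration",
    "synthesized_fraction", "concentration_fold_change",
    "fit_partitioning", "PartitioningModel", "PartitioningResults",
]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def segregation_fraction(c_germ: float, c_soma: float,
                         v_germ: float, v_soma: float) -> float:
    """Fraction of the mother's amount inherited by the germline daughter."""
    if min(c_germ, c_soma) < 0 or min(v_germ, v_soma) <= 0:
        raise ValueError("concentrations must be >= 0 and volumes > 0")
    a_g, a_s = c_germ * v_germ, c_soma * v_soma
    if a_g + a_s == 0:
        raise ValueError("zero total amount: fraction undefined")
    return a_g / (a_g + a_s)


def predict_inherited_concentration(c0_nM: float, phi: float,
                                    fractions) -> float:
    """Concentration from maternal inheritance alone: c0 * phi * prod(f_i).

    ``phi`` is the fold decrease in cell volume from the zygote to the
    final cell of the chain (>= 1); each f_i must lie strictly in (0, 1).
    An empty fraction list returns c0 * phi.
    """
    if c0_nM < 0:
        raise ValueError("c0 must be >= 0")
    if phi < 1:
        raise ValueError("volume fold decrease phi must be >= 1")
    fractions = list(fractions)
    if any(not 0.0 < f < 1.0 for f in fractions):
        raise ValueError("segregation fractions must be in (0, 1)")
    return c0_nM * phi * float(np.prod(fractions)) if fractions else c0_nM * phi


def synthesized_fraction(predicted_nM: float, observed_nM: float) -> float:
    """Share of the observed concentration not explained by inheritance.

    1 - predicted/observed, clamped to [0, 1] with a warning if the raw
    value falls outside (predicted exceeding observed, or negative inputs
    from noise).
    """
    if observed_nM <= 0:
        raise ValueError("observed concentration must be > 0")
    raw = 1.0 - predicted_nM / observed_nM
    if not 0.0 <= raw <= 1.0:
        warnings.warn(f"synthesized fraction {raw:.3f} clamped to [0, 1]",
                      stacklevel=2)
        return float(min(max(raw, 0.0), 1.0))
    return raw


def concentration_fold_change(c_start_nM: float, c_end_nM: float) -> float:
    if c_start_nM <= 0:
        raise ValueError("starting concentration must be > 0")
    return c_end_nM / c_start_nM


# ---------------------------------------------------------------------------
# measurements from time-lapses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DivisionMeasurement:
    """Daughter volumes and relative concentrations just after one division."""

    mother: str
    germ_daughter: str
    soma_daughter: str
    v_germ_pL: float
    v_soma_pL: float
    c_germ_rel: float            # normalized so that the somatic daughter = 1
    c_soma_rel: float = 1.0

    def __post_init__(self):
        if self.v_germ_pL <= 0 or self.v_soma_pL <= 0:
            raise ValueError("volumes must be > 0")
        if self.c_germ_rel < 0 or self.c_soma_rel < 0:
            raise ValueError("concentrations must be >= 0")

    @property
    def fraction(self) -> float:
        return segregation_fraction(self.c_germ_rel, self.c_soma_rel,
                                    self.v_germ_pL, self.v_soma_pL)


@dataclass(frozen=True)
class InheritancePrediction:
    """Inheritance-only prediction and its decomposition against observation."""

    c0_nM: float
    volume_fold_decrease: float
    fractions: tuple[float, ...]
    predicted_nM: float
    observed_nM: float | None = None
    synthesized_fraction: float | None = None


def fit_partitioning(traces: pd.DataFrame, masks_per_frame: list,
                     volumes_pL: dict[str, float],
                     divisions) -> list[DivisionMeasurement]:
    """Extract division measurements from per-cell intensity traces.

    ``traces`` is tidy with columns time_s, cell, intensity (background-
    corrected); ``masks_per_frame`` gives, per frame, which cells exist
    (any object with a ``cells`` mapping, e.g. CompartmentMasks);
    ``divisions`` is an iterable of (mother, germ_daughter, soma_daughter)
    triples.  "Just after division" is the first frame in which both
    daughter masks exist; relative concentrations are normalized so the
    somatic daughter equals 1.
    """
    frame_cells = [set(m.cells) for m in masks_per_frame]
    times = np.sort(traces["time_s"].unique())
    if len(times) != len(frame_cells):
        raise ValueError("traces and masks_per_frame disagree on frame count")
    out = []
    for mother, germ, soma in divisions:
        for d in (germ, soma):
            if d not in volumes_pL:
                raise ValueError(f"no volume for daughter {d!r}")
        idx = next((i for i, cells in enumerate(frame_cells)
                    if germ in cells and soma in cells), None)
        if idx is None:
            raise ValueError(f"daughters of {mother!r} never co-exist in the masks")
        t = times[idx]
        frame = traces[traces["time_s"] == t].set_index("cell")["intensity"]
        if germ not in frame.index or soma not in frame.index:
            raise ValueError(f"missing daughter trace at t={t}")
        c_soma = float(frame[soma])
        if c_soma <= 0:
            raise ValueError("somatic daughter intensity must be > 0 to normalize")
        out.append(DivisionMeasurement(
            mother=mother, germ_daughter=germ, soma_daughter=soma,
            v_germ_pL=volumes_pL[germ], v_soma_pL=volumes_pL[soma],
            c_germ_rel=float(frame[germ]) / c_soma, c_soma_rel=1.0))
    return out


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class PartitioningModel:
    """Mass-balance partitioning model over a table of division measurements.

    Parameters
    ----------
    measurements
        One or more `DivisionMeasurement` per division (replicate embryos
        allowed; fractions are averaged per mother cell).

    Examples
    --------
    >>> m1 = DivisionMeasurement("P0", "P1", "AB", 10.1, 14.7, 2.03)
    >>> m2 = DivisionMeasurement("P1", "P2", "EMS", 4.2, 6.1, 1.91)
    >>> res = PartitioningModel([m1, m2]).fit(c0_nM=92, phi=6.4, observed_nM=424)
    >>> round(res.predicted_nM)
    195
    """

    def __init__(self, measurements):
        self.measurements = list(measurements)
        if not self.measurements:
            raise ValueError("need at least one division measurement")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PartitioningModel":
        """Build from a tidy table with columns mother, daughter, role
        (germline|somatic), volume_pL, rel_conc."""
        need = {"mother", "daughter", "role", "volume_pL", "rel_conc"}
        if not need <= set(df.columns):
            raise ValueError(f"measurement table needs columns {sorted(need)}")
        ms = []
        for (mother, rep), grp in df.groupby(
                ["mother", df.get("embryo", pd.Series(0, index=df.index))], sort=False):
            roles = grp.set_index("role")
            if not {"germline", "somatic"} <= set(roles.index):
                raise ValueError(f"division of {mother!r} needs both daughter roles")
            g, s = roles.loc["germline"], roles.loc["somatic"]
            ms.append(DivisionMeasurement(
                mother=mother, germ_daughter=g["daughter"], soma_daughter=s["daughter"],
                v_germ_pL=float(g["volume_pL"]), v_soma_pL=float(s["volume_pL"]),
                c_germ_rel=float(g["rel_conc"]), c_soma_rel=float(s["rel_conc"])))
        return cls(ms)

    def fit(self, c0_nM: float | None = None, phi: float | None = None,
            observed_nM: float | None = None,
            division_order: list[str] | None = None) -> "PartitioningResults":
        """Compute per-division segregation fractions and, if ``c0_nM`` and
        ``phi`` are given, the inheritance-only prediction (plus the
        synthesized fraction when ``observed_nM`` is given)."""
        by_mother: dict[str, list[DivisionMeasurement]] = {}
        for m in self.measurements:
            by_mother.setdefault(m.mother, []).append(m)
        order = division_order or list(by_mother)
        fractions, se = {}, {}
        for mother in order:
            fs = [m.fraction for m in by_mother[mother]]
            fractions[mother] = float(np.mean(fs))
            se[mother] = float(np.std(fs, ddof=1) / math.sqrt(len(fs))) if len(fs) > 1 else float("nan")
        prediction = None
        if c0_nM is not None and phi is not None:
            pred = predict_inherited_concentration(c0_nM, phi, list(fractions.values()))
            synth = (synthesized_fraction(pred, observed_nM)
                     if observed_nM is not None else None)
            prediction = InheritancePrediction(
                c0_nM=c0_nM, volume_fold_decrease=phi,
                fractions=tuple(fractions.values()), predicted_nM=pred,
                observed_nM=observed_nM, synthesized_fraction=synth)
        return PartitioningResults(self, fractions, se, prediction)


class PartitioningResults:
    """Fitted segregation fractions and the inheritance decomposition."""

    def __init__(self, model, fractions, stderr, prediction):
        self.model = model
        self.fractions = fractions          # mother -> mean fraction
        self.stderr = stderr                # mother -> SE across replicates
        self.prediction = prediction        # InheritancePrediction | None

    @property
    def percents(self) -> dict[str, int]:
        """Fractions as printed integer percentages (half-up)."""
        return {m: int(round_half_up(100 * f)) for m, f in self.fractions.items()}

    @property
    def predicted_nM(self) -> float | None:
        return None if self.prediction is None else self.prediction.predicted_nM

    @property
    def synthesized_fraction(self) -> float | None:
        return None if self.prediction is None else self.prediction.synthesized_fraction

    def fold_change(self) -> float | None:
        p = self.prediction
        if p is None or p.observed_nM is None:
            return None
        return concentration_fold_change(p.c0_nM, p.observed_nM)

    def summary(self) -> str:
        lines = ["Partitioning mass-balance results",
                 "=" * 44,
                 f"{'division':<12}{'fraction':>10}{'percent':>9}{'SE':>9}"]
        for m, f in self.fractions.items():
            se = self.stderr[m]
            lines.append(f"{m + ' -> ':<12}{f:>10.4f}{self.percents[m]:>8}%"
                         f"{se:>9.4f}" if math.isfinite(se) else
                         f"{m + ' -> ':<12}{f:>10.4f}{self.percents[m]:>8}%{'--':>9}")
        p = self.prediction
        if p is not None:
            lines += ["-" * 44,
                      f"zygote concentration (c0)  : {p.c0_nM:8.1f} nM",
                      f"volume fold decrease (phi) : {p.volume_fold_decrease:8.2f}",
                      f"inherited prediction       : {p.predicted_nM:8.1f} nM"]
            if p.observed_nM is not None:
                lines += [f"observed concentration     : {p.observed_nM:8.1f} nM",
                          f"synthesized fraction       : {p.synthesized_fraction:8.2f}",
                          f"fold change (obs/c0)       : {self.fold_change():8.2f}"]
        return "\n".join(lines)

    def __repr__(self):  # pragma: no cover
        return f"<PartitioningResults fractions={self.fractions}>"
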