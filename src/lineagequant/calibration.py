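"""Absolute concentration estimation from bath-calibrated images.

The estimator follows the classic external-standard protocol: the embryo
is imaged in a bath of recombinant GFP at known concentration; after
flat-field correction, camera-background subtraction and an
autofluorescence correction (measured once on untagged N2 embryos bathed
in the same solution), the intracellular concentration is the bath
concentration multiplied by the intracellular/bath intensity ratio:

    C_in = C_bath * (I_in - bg - af) / (I_bath - bg)

Flat-field correction divides each image pixel-wise by the average of
several bath-only images and rescales by the maximum of that average, so
a perfectly uniform reference leaves the image unchanged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .masks import CompartmentMasks

__all__ = [
    "IlluminationReference", "ConcentrationEstimate",
    "build_illumination_reference", "flatfield_correct",
    "measure_camera_background", "measure_autofluorescence",
    "estimate_concentration", "posterior_anterior_ratio",
]


@dataclass(frozen=True)
class IlluminationReference:
    """Averaged bath-only image used for flat-field correction."""

    mean_bath_image: np.ndarray
    max_value: float
    n_images_averaged: int

    def __post_init__(self):
        if self.n_images_averaged < 1:
            raise ValueError("n_images_averaged must be >= 1")
        if not math.isclose(self.max_value, float(np.max(self.mean_bath_image))):
            raise ValueError("max_value must equal max(mean_bath_image)")


@dataclass(frozen=True)
class ConcentrationEstimate:
    cell: str
    compartment: str            # total | cytoplasm | nucleus
    conc_nM: float
    n_pixels: int
    corrected_mean_counts: float

    def __post_init__(self):
        if self.n_pixels <= 0:
            raise ValueError("n_pixels must be > 0")
        if not math.isfinite(self.conc_nM):
            raise ValueError("conc_nM must be finite")


def build_illumination_reference(bath_images) -> IlluminationReference:
    """Pixel-wise mean of >= 1 bath-only images."""
    imgs = [np.asarray(im, dtype=float) for im in bath_images]
    if not imgs:
        raise ValueError("need at least one bath image")
    shape = imgs[0].shape
    if any(im.shape != shape for im in imgs):
        raise ValueError("bath images have mismatched shapes")
    mean = np.mean(imgs, axis=0)
    return IlluminationReference(mean_bath_image=mean,
                                 max_value=float(mean.max()),
                                 n_images_averaged=len(imgs))


def flatfield_correct(image: np.ndarray, ref: IlluminationReference) -> np.ndarray:
    """out = image / mean_bath_image * max(mean_bath_image), pixel-wise."""
    image = np.asarray(image, dtype=float)
    if image.shape != ref.mean_bath_image.shape:
        raise ValueError("image and reference shapes differ")
    if np.any(ref.mean_bath_image == 0):
        raise ValueError("illumination reference contains zero pixels")
    return image / ref.mean_bath_image * ref.max_value


def _masked_mean(image: np.ndarray, mask: np.ndarray,
                 saturation: float | None = None) -> tuple[float, int]:
    vals = image[mask]
    if vals.size == 0:
        raise ValueError("empty region")
    if saturation is not None:
        sat = vals >= saturation
        if sat.any():
            warnings.warn(f"excluding {int(sat.sum())} saturated pixel(s) from mean",
                          stacklevel=3)
            vals = vals[~sat]
            if vals.size == 0:
                raise ValueError("region fully saturated")
    return float(vals.mean()), int(vals.size)


def measure_camera_background(source: np.ndarray, mode: str = "m9_blank",
                              mask: np.ndarray | None = None) -> float:
    """Mean camera counts in a signal-free region.

    ``mode="m9_blank"``: mean of a blank-buffer image (the whole frame, or
    ``mask`` if given) -- the correct mode for bath-containing frames,
    where everything outside the embryo fluoresces.
    ``mode="outside_embryo"``: mean over ``mask`` (a region outside the
    embryo) of the given image -- appropriate when no bath is present.
    """
    source = np.asarray(source, dtype=float)
    if mode == "m9_blank":
        region = np.ones(source.shape, bool) if mask is None else mask
    elif mode == "outside_embryo":
        if mask is None:
            raise ValueError("outside_embryo mode requires a mask")
        region = mask
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mean, _ = _masked_mean(source, region)
    return mean


def measure_autofluorescence(n2_scene_image: np.ndarray, masks: CompartmentMasks,
                             camera_bg: float,
                             ref: IlluminationReference | None = None) -> float:
    """Mean embryo-interior counts of an untagged-embryo scene, minus camera
    background.  Negative values (from noise) are propagated as-is."""
    img = np.asarray(n2_scene_image, dtype=float)
    if ref is not None:
        img = flatfield_correct(img, ref)
    if not masks.embryo.any():
        raise ValueError("empty embryo mask")
    mean, _ = _masked_mean(img, masks.embryo)
    return mean - camera_bg


def estimate_concentration(image: np.ndarray, masks: CompartmentMasks,
                           bath_nM: float, camera_bg: float,
                           autofluor_counts: float = 0.0,
                           ref: IlluminationReference | None = None,
                           saturation: float | None = None) -> list[ConcentrationEstimate]:
    """Estimate nM concentrations for every masked compartment.

    Flat-field correction (if a reference is given) is applied first; the
    bath intensity is background-corrected, each compartment intensity is
    background- and autofluorescence-corrected, and concentrations follow
    from the bath ratio.  Estimates are emitted for the total, cytoplasm
    and nucleus of every cell that has a mask.
    """
    if bath_nM <= 0:
        raise ValueError("bath_nM must be > 0")
    if not masks.bath.any() or not masks.cells:
        raise ValueError("need a non-empty bath mask and at least one cell mask")
    img = np.asarray(image, dtype=float)
    if ref is not None:
        img = flatfield_correct(img, ref)
    i_bath, _ = _masked_mean(img, masks.bath, saturation)
    i_bath -= camera_bg
    if i_bath <= 0:
        raise ValueError("bath intensity <= camera background: uncalibratable")
    out = []
    for cell, cm in masks.cells.items():
        for comp, m in (("total", cm.total), ("cytoplasm", cm.cytoplasm),
                        ("nucleus", cm.nucleus)):
            if not m.any():
                continue
            try:
                mean, n = _masked_mean(img, m, saturation)
            except ValueError as err:
                if "saturated" in str(err):
                    warnings.warn(f"{cell}/{comp} fully saturated; "
                                  "no estimate emitted", stacklevel=2)
                    continue
                raise
            i_in = mean - camera_bg - autofluor_counts
            out.append(ConcentrationEstimate(
                cell=cell, compartment=comp,
                conc_nM=bath_nM * i_in / i_bath,
                n_pixels=n, corrected_mean_counts=i_in))
    return out


def estimates_to_frame(estimates: list[ConcentrationEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in estimates])


def posterior_anterior_ratio(image: np.ndarray, embryo_mask: np.ndarray,
                             orientation: float, camera_bg: float) -> float:
    """Posterior/anterior mean-intensity ratio of the embryo.

    The embryo is split by the perpendicular bisector of the AP axis
    through the mask centroid; the posterior half lies in the +axis
    direction.  Both half-means are camera-background corrected.
    """
    if not embryo_mask.any():
        raise ValueError("empty embryo mask")
    img = np.asarray(image, dtype=float)
    ys, xs = np.nonzero(embryo_mask)
    cy, cx = ys.mean(), xs.mean()
    u = (xs - cx) * math.cos(orientation) + (ys - cy) * math.sin(orientation)
    post = img[ys[u > 0], xs[u > 0]].mean() - camera_bg
    ant = img[ys[u <= 0], xs[u <= 0]].mean() - camera_bg
    if ant <= 0:
        raise ValueError("anterior mean <= camera background")
    return float(post / ant)
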