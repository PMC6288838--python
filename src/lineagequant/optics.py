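"""Imaging model: illumination field, camera offset and noise.

The camera model is Poisson shot noise on the signal, multiplied by a
position-dependent illumination gain, plus a constant offset and Gaussian
read noise -- the standard approximation for an EMCCD behind a spinning
disk.  ``photons_per_nM`` is the single linearity constant converting
fluorophore concentration to expected counts per pixel; it is a free
parameter of the synthetic scenes (real acquisitions never report it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._util import rng_from

__all__ = ["OpticsModel", "vignette_field"]


def vignette_field(shape: tuple[int, int], strength: float = 0.25) -> np.ndarray:
    """Radially symmetric multiplicative gain map, 1.0 at the frame centre.

    ``strength`` is the fractional falloff at the frame corner; 0 gives a
    perfectly flat field.
    """
    if not 0 <= strength < 1:
        raise ValueError("vignette strength must be in [0, 1)")
    ny, nx = shape
    y = np.arange(ny) - (ny - 1) / 2
    x = np.arange(nx) - (nx - 1) / 2
    r2 = (y[:, None] ** 2 + x[None, :] ** 2)
    r2max = ((ny - 1) / 2) ** 2 + ((nx - 1) / 2) ** 2
    return 1.0 - strength * r2 / r2max


@dataclass(frozen=True)
class OpticsModel:
    """Imaging conditions for a synthetic acquisition.

    Parameters
    ----------
    illumination_field
        2D multiplicative gain map, strictly positive, peak 1.0.
    camera_offset
        Additive counts present in every pixel (the "camera background").
    read_noise_sd
        Standard deviation of the additive Gaussian read noise, in counts.
    photons_per_nM
        Expected counts per pixel per nM of fluorophore at unit gain.
    autofluorescence_nM_equiv
        Embryo-interior background signal, expressed in nM equivalents.
    """

    illumination_field: np.ndarray
    camera_offset: float = 100.0
    read_noise_sd: float = 5.0
    photons_per_nM: float = 10.0
    autofluorescence_nM_equiv: float = 15.0

    def __post_init__(self):
        f = np.asarray(self.illumination_field, dtype=float)
        if f.ndim != 2:
            raise ValueError("illumination_field must be 2D")
        if not np.all(f > 0):
            raise ValueError("illumination_field must be positive everywhere")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.photons_per_nM <= 0:
            raise ValueError("photons_per_nM must be > 0")
        object.__setattr__(self, "illumination_field", f)

    @property
    def shape(self) -> tuple[int, int]:
        return self.illumination_field.shape

    @classmethod
    def default(cls, shape: tuple[int, int] = (128, 192),
                vignette: float = 0.25, **kw) -> "OpticsModel":
        return cls(illumination_field=vignette_field(shape, vignette), **kw)

    def flat(self) -> "OpticsModel":
        """Same camera, perfectly uniform illumination."""
        return replace(self, illumination_field=np.ones(self.shape))

    def noiseless(self) -> "OpticsModel":
        return replace(self, read_noise_sd=0.0)

    # -- rendering -------------------------------------------------------

    def render(self, conc_nM: np.ndarray, rng=None, noise: bool = True) -> np.ndarray:
        """Render a concentration map (nM per pixel) to camera counts.

        counts = Poisson(photons_per_nM * nM) * field + offset + N(0, read_sd)

        With ``noise=False`` the expectation is returned instead (shot and
        read noise both suppressed).
        """
        conc = np.asarray(conc_nM, dtype=float)
        if conc.shape != self.shape:
            raise ValueError(f"concentration map shape {conc.shape} != optics shape {self.shape}")
        if np.any(conc < 0):
            raise ValueError("negative concentration in scene")
        expected = self.photons_per_nM * conc
        if noise:
            rng = rng_from(rng)
            signal = rng.poisson(expected).astype(float)
        else:
            signal = expected
        img = signal * self.illumination_field + self.camera_offset
        if noise and self.read_noise_sd > 0:
            img = img + rng.normal(0.0, self.read_noise_sd, size=img.shape)
        return img

    def pixel_noise_sd(self, conc_nM: float) -> float:
        """Per-pixel count SD at a given local concentration (field ~ 1)."""
        return float(np.sqrt(self.photons_per_nM * conc_nM + self.read_noise_sd ** 2))
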