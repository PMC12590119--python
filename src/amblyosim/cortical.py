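"""Cortical activation spread on orientation-preference maps.

A fellow-eye stimulus drives each cortical pixel according to the circular
orientation distance between the pixel's preferred orientation and the
stimulus; an amblyopic eye drives pixels through every grating filter in the
fitted percept, each weighted by a Gaussian of its orientation offset from
the stimulus.  Spread is the count of pixels above 70% of the per-eye
maximum response, and the spread ratio (amblyopic/fellow) summarizes how far
activation fans out beyond the stimulus orientation columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .percept import FilterSet

__all__ = [
    "OrientationMap",
    "ActivationMap",
    "SpreadResult",
    "circ_dist",
    "fellow_response",
    "grating_weight",
    "amblyopic_response",
    "spread",
    "spread_ratio",
    "map_metrics",
]


@dataclass
class OrientationMap:
    """Grid of preferred orientations in degrees [0, 180) with mm calibration."""

    preferred_orientation: np.ndarray
    mm_per_pixel: float
    provenance: str = "file"

    def __post_init__(self) -> None:
        self.preferred_orientation = np.asarray(self.preferred_orientation, dtype=float) % 180.0
        if self.preferred_orientation.ndim != 2:
            raise ValueError("orientation map must be 2-D")
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.preferred_orientation.shape


@dataclass
class ActivationMap:
    response: np.ndarray
    eye: str
    threshold_fraction: float = 0.7

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        if not np.all(np.isfinite(self.response)):
            raise ValueError("responses must be finite")
        if np.any(self.response < 0):
            raise ValueError("responses must be >= 0")


@dataclass
class SpreadResult:
    n_active_fellow: int
    n_active_amblyopic: int
    spread_ratio: float


def circ_dist(o1: Union[float, np.ndarray], o2: Union[float, np.ndarray]):
    """Circular orientation distance scaled to [0, 1] (period 180 degrees).

    |delta|/90 for |delta| <= 90, else (180 - |delta|)/90, after reducing the
    raw difference modulo 180.  Identical orientations give 0, orthogonal
    ones give 1.
    """
    delta = np.abs(np.asarray(o1, dtype=float) - np.asarray(o2, dtype=float)) % 180.0
    d = np.where(delta <= 90.0, delta, 180.0 - delta) / 90.0
    return float(d) if d.ndim == 0 else d


def fellow_response(omap: OrientationMap, stim_orientation: float) -> ActivationMap:
    """Per-pixel fellow-eye response FR = 1 - circ_dist(O_C, O_S), in [0, 1]."""
    fr = 1.0 - circ_dist(omap.preferred_orientation, stim_orientation)
    return ActivationMap(fr, eye="fellow")


def grating_weight(o_g: float, o_s: float, sigma: float = 0.2) -> float:
    """Gaussian weight exp(-circ_dist(o_g, o_s)^2 / (2 sigma^2)) of a filter."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    d = circ_dist(o_g, o_s)
    return float(np.exp(-(d**2) / (2.0 * sigma**2)))


def amblyopic_response(
    omap: OrientationMap,
    filters: FilterSet,
    stim_orientation: float,
    sigma: float = 0.2,
) -> ActivationMap:
    """Per-pixel amblyopic response: sum over filters of (1 - circ_dist) * W_G."""
    if len(filters) == 0:
        raise ValueError("empty filter set")
    ar = np.zeros(omap.shape)
    for p in filters.filters:
        w_g = grating_weight(p.orientation, stim_orientation, sigma)
        ar += (1.0 - circ_dist(omap.preferred_orientation, p.orientation)) * w_g
    return ActivationMap(ar, eye="amblyopic")


def spread(act: ActivationMap) -> int:
    """Count of pixels at or above threshold_fraction * max response."""
    peak = float(act.response.max())
    if peak <= 0:
        raise ValueError("all-zero activation map: maximum response undefined")
    return int(np.count_nonzero(act.response >= act.threshold_fraction * peak))


def spread_ratio(fellow: ActivationMap, amblyopic: ActivationMap) -> SpreadResult:
    """Amblyopic/fellow ratio of strongly activated pixel counts."""
    if fellow.response.shape != amblyopic.response.shape:
        raise ValueError("activation maps must share shape")
    n_f = spread(fellow)
    n_a = spread(amblyopic)
    return SpreadResult(n_f, n_a, n_a / n_f)


def map_metrics(omap: OrientationMap) -> dict:
    """Descriptive statistics of an orientation map.

    Column width: half the dominant wavelength of the complex field
    exp(2i*theta), estimated from the power-weighted radially averaged
    spectrum (mean and SD over the band above half-peak power).  Pinwheel
    density: count of +-1/2 phase singularities per mm^2.
    """
    theta = np.deg2rad(omap.preferred_orientation)
    z = np.exp(2j * theta)
    z = z - z.mean()
    ny, nx = z.shape
    if min(ny, nx) < 20:
        raise ValueError("map too small for spectral column-width estimate")

    power = np.abs(np.fft.fft2(z)) ** 2
    fy = np.fft.fftfreq(ny, d=omap.mm_per_pixel)
    fx = np.fft.fftfreq(nx, d=omap.mm_per_pixel)
    fr = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2).ravel()
    pw = power.ravel().copy()
    pw[fr == 0] = 0.0  # DC removed with the mean

    if pw.max() <= 0:
        return {
            "column_width_mm": np.nan,
            "column_width_sd_mm": np.nan,
            "pinwheel_count": 0,
            "pinwheel_density_per_mm2": 0.0,
        }
    band = pw >= 0.5 * pw.max()
    w = pw[band]
    half_wavelength = 0.5 / fr[band]
    mean_width = float(np.average(half_wavelength, weights=w))
    sd_width = float(np.sqrt(np.average((half_wavelength - mean_width) ** 2, weights=w)))

    # pinwheels: winding number of the doubled-angle phase around each plaquette
    phase = np.angle(np.exp(2j * theta))
    d1 = _wrap(phase[:-1, 1:] - phase[:-1, :-1])
    d2 = _wrap(phase[1:, 1:] - phase[:-1, 1:])
    d3 = _wrap(phase[1:, :-1] - phase[1:, 1:])
    d4 = _wrap(phase[:-1, :-1] - phase[1:, :-1])
    winding = d1 + d2 + d3 + d4
    n_pinwheels = int(np.count_nonzero(np.abs(winding) > np.pi))
    area_mm2 = ny * nx * omap.mm_per_pixel**2
    return {
        "column_width_mm": mean_width,
        "column_width_sd_mm": sd_width,
        "pinwheel_count": n_pinwheels,
        "pinwheel_density_per_mm2": n_pinwheels / area_mm2,
    }


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2.0 * np.pi) - np.pi
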