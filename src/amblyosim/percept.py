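"""Percept synthesis from rectified sinusoidal grating filters.

A distorted visual percept is modeled as the saturated weighted sum of
"cortical filters": sinusoidal gratings shifted by a dark/light duty-cycle
constant K and rectified at a saturation threshold T.  A fellow (non-amblyopic)
eye corresponds to K = 0; amblyopic eyes use K in [-1, 1], which thickens dark
(K < 0) or bright (K > 0) bars of the percept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GratingParams",
    "Geometry",
    "ImageField",
    "FilterSet",
    "AliasingError",
    "make_grating",
    "make_filter",
    "filter_weight",
    "synthesize_percept",
]


class AliasingError(ValueError):
    """Requested spatial frequency at or above the Nyquist limit."""


@dataclass(frozen=True)
class GratingParams:
    """Six per-filter parameters of the percept model.

    orientation
        Degrees in [0, 180); 0 deg = horizontal bars (luminance modulated
        along the vertical axis), increasing counterclockwise.
    spatial_frequency
        Cycles per degree of visual angle (> 0).
    phase
        Degrees in [0, 360); phase 0 puts a zero-crossing at the center.
    duty_constant
        K, dimensionless in [-1, 1].  Zero for fellow-eye simulations.
    saturation_threshold
        T, dimensionless in [0, 2]; the filter is clipped to [-T, T].
    amblyopia_constant
        A, dimensionless in [0, 1]; scales the stimulus-drive weight.
    """

    orientation: float
    spatial_frequency: float
    phase: float = 0.0
    duty_constant: float = 0.0
    saturation_threshold: float = 1.0
    amblyopia_constant: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.spatial_frequency) or self.spatial_frequency <= 0:
            raise ValueError(f"spatial_frequency must be > 0, got {self.spatial_frequency}")
        if not -1.0 <= self.duty_constant <= 1.0:
            raise ValueError(f"duty_constant K must lie in [-1, 1], got {self.duty_constant}")
        if not 0.0 <= self.saturation_threshold <= 2.0:
            raise ValueError(
                f"saturation_threshold T must lie in [0, 2], got {self.saturation_threshold}"
            )
        if not 0.0 <= self.amblyopia_constant <= 1.0:
            raise ValueError(
                f"amblyopia_constant A must lie in [0, 1], got {self.amblyopia_constant}"
            )
        object.__setattr__(self, "orientation", float(self.orientation) % 180.0)
        object.__setattr__(self, "phase", float(self.phase) % 360.0)

    def with_(self, **kwargs) -> "GratingParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Geometry:
    """Square stimulus geometry: field extent (deg) and sampling density."""

    extent_deg: float = 3.2
    pixels_per_degree: float = 80.0

    def __post_init__(self) -> None:
        if self.extent_deg <= 0 or self.pixels_per_degree <= 0:
            raise ValueError("extent_deg and pixels_per_degree must be positive")

    @property
    def n_pixels(self) -> int:
        return int(round(self.extent_deg * self.pixels_per_degree))

    @property
    def nyquist_cpd(self) -> float:
        return self.pixels_per_degree / 2.0

    def coordinates_deg(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) meshgrids in degrees, origin at the field center."""
        n = self.n_pixels
        c = (np.arange(n) - (n - 1) / 2.0) / self.pixels_per_degree
        return np.meshgrid(c, c, indexing="xy")

    def aperture(self) -> np.ndarray:
        """Inscribed circular aperture mask."""
        x, y = self.coordinates_deg()
        return x**2 + y**2 <= (self.extent_deg / 2.0) ** 2


@dataclass
class ImageField:
    """Square luminance-contrast image with angular calibration.

    Values are luminance contrast in [-1, 1] relative to the mean background;
    pixels outside the inscribed circular aperture are 0 (= background).
    """

    values: np.ndarray
    extent_deg: float
    pixels_per_degree: float
    aperture: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"values must be square 2-D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.aperture is None:
            self.aperture = self.geometry.aperture()
        self.aperture = np.asarray(self.aperture, dtype=bool)
        if self.aperture.shape != self.values.shape:
            raise ValueError("aperture mask must match values shape")

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.extent_deg, self.pixels_per_degree)

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    def same_geometry(self, other: "ImageField") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.extent_deg, other.extent_deg)
            and np.isclose(self.pixels_per_degree, other.pixels_per_degree)
        )

    def masked(self) -> np.ndarray:
        """Values with the outside of the aperture forced to background 0."""
        return np.where(self.aperture, self.values, 0.0)


@dataclass
class FilterSet:
    """Ordered collection of cortical filters with explicit weights."""

    filters: list[GratingParams]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.filters = list(self.filters)
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if len(self.filters) < 1:
            raise ValueError("FilterSet requires at least one filter")
        if self.weights.shape != (len(self.filters),):
            raise ValueError("one weight per filter required")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    def __len__(self) -> int:
        return len(self.filters)


def make_grating(params: GratingParams, geometry: Geometry) -> ImageField:
    """Sinusoidal grating G on the given geometry, zero outside the aperture.

    G = sin(2*pi*f*(x*sin(theta) + y*cos(theta)) + phi) with theta = 0 giving
    horizontal bars (constant rows).
    """
    if params.spatial_frequency >= geometry.nyquist_cpd:
        raise AliasingError(
            f"spatial_frequency {params.spatial_frequency} cpd >= Nyquist "
            f"{geometry.nyquist_cpd} cpd for {geometry.pixels_per_degree} px/deg"
        )
    x, y = geometry.coordinates_deg()
    theta = np.deg2rad(params.orientation)
    phi = np.deg2rad(params.phase)
    arg = 2.0 * np.pi * params.spatial_frequency * (x * np.sin(theta) + y * np.cos(theta)) + phi
    mask = geometry.aperture()
    values = np.where(mask, np.sin(arg), 0.0)
    return ImageField(values, geometry.extent_deg, geometry.pixels_per_degree, mask)


def make_filter(params: GratingParams, geometry: Geometry) -> ImageField:
    """Cortical filter F = Sat(G + K): add the duty constant, clip to [-T, T]."""
    g = make_grating(params, geometry)
    t = params.saturation_threshold
    values = np.clip(g.values + params.duty_constant, -t, t)
    values = np.where(g.aperture, values, 0.0)
    return ImageField(values, g.extent_deg, g.pixels_per_degree, g.aperture)


def filter_weight(stimulus: ImageField, params: GratingParams) -> float:
    """Stimulus-drive weight W = A * Avg(S . G) over the aperture.

    The average product at zero lag (normalized cross-correlation reading of
    the stimulus/grating convolution): ~0.5 for a grating matched to the
    stimulus, ~0 for an orthogonal one.
    """
    grating = make_grating(params, stimulus.geometry)
    if not stimulus.same_geometry(grating):
        raise ValueError("stimulus and grating geometry mismatch")
    mask = stimulus.aperture & grating.aperture
    avg = float(np.mean(stimulus.values[mask] * grating.values[mask]))
    return params.amblyopia_constant * avg


def synthesize_percept(
    fs: FilterSet,
    geometry: Geometry,
    saturation_bound: float = 1.0,
    soft: bool = False,
) -> ImageField:
    """Simulated percept: saturated weighted sum of the cortical filters.

    The outer saturation is hard clipping to [-saturation_bound, +bound] by
    default; ``soft=True`` switches to a tanh soft saturation of the same
    asymptotic bound.
    """
    if len(fs) == 0:  # defensive; FilterSet already enforces >= 1
        raise ValueError("empty filter set")
    total = np.zeros((geometry.n_pixels, geometry.n_pixels))
    mask = geometry.aperture()
    for p, w in zip(fs.filters, fs.weights):
        total += w * make_filter(p, geometry).values
    if soft:
        values = saturation_bound * np.tanh(total / saturation_bound)
    else:
        values = np.clip(total, -saturation_bound, saturation_bound)
    values = np.where(mask, values, 0.0)
    return ImageField(values, geometry.extent_deg, geometry.pixels_per_degree, mask)


def weighted_filter_sum(fs: FilterSet, geometry: Geometry) -> np.ndarray:
    """Unsaturated weighted sum of filters (internal helper for the fitter)."""
    total = np.zeros((geometry.n_pixels, geometry.n_pixels))
    for p, w in zip(fs.filters, fs.weights):
        total += w * make_filter(p, geometry).values
    return total
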