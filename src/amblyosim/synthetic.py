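"""Synthetic stand-ins for the unavailable experimental inputs.

The original subject drawings, contrast-sensitivity tables, and cortical
maps are not deposited anywhere, so every consumer of those inputs is tested
against generated data with known ground truth: distorted "drawings" built
from known filter sets plus hand-tremor-like spatial jitter and pixel noise,
Gaussian CSF tables, band-pass-noise orientation maps with pinwheel
structure, and an end-to-end cohort whose contrast-sensitivity deficit is
generatively linked to its percept distortion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .cortical import OrientationMap
from .metrics import csf_value
from .percept import FilterSet, Geometry, GratingParams, ImageField, make_grating, synthesize_percept

__all__ = [
    "SyntheticDrawingSpec",
    "SyntheticCohortSpec",
    "SyntheticSubject",
    "STANDARD_SFS_CPD",
    "FELLOW_CSF_PARAMS",
    "gen_drawing",
    "gen_csf_pair",
    "gen_orientation_map",
    "gen_cohort",
    "default_battery",
]

# stimulus battery of the emulated drawing experiment
STANDARD_SFS_CPD = (1.25, 2.5, 5.0, 10.0, 16.0)

# fellow-eye CSF: ~100 sensitivity at low SF, < 10 at high SF
FELLOW_CSF_PARAMS = {"g0": 2.0, "g": 98.0, "sf_p": 3.0, "sigma": 2.0}


@dataclass
class SyntheticDrawingSpec:
    true_filters: FilterSet
    pixel_noise_sd: float = 0.02
    jitter_amplitude_deg: float = 0.02  # <= 0.05 deg hand-tremor warp
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_noise_sd < 0 or self.jitter_amplitude_deg < 0:
            raise ValueError("noise and jitter must be >= 0")


@dataclass
class SyntheticCohortSpec:
    n_subjects: int = 7
    deficit_range: tuple[float, float] = (0.0, 3.0)
    distortion_noise_sd: float = 0.05
    rng_seed: int = 0
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need >= 3 subjects for correlation")


@dataclass
class SyntheticSubject:
    subject_id: str
    deficit: float
    stimulus_params: GratingParams
    stimulus: ImageField
    drawing: ImageField
    truth: FilterSet
    csf_fellow: pd.DataFrame
    csf_amblyopic: pd.DataFrame
    rng_seed: int


def gen_drawing(spec: SyntheticDrawingSpec, geometry: Geometry) -> tuple[ImageField, FilterSet]:
    """Distorted drawing from known filters: percept + smooth warp + pixel noise.

    The warp is a low-frequency two-component sinusoidal displacement field
    emulating drawing inaccuracy; the truth filter set is returned for
    parameter-recovery scoring.
    """
    rng = np.random.default_rng(spec.rng_seed)
    percept = synthesize_percept(spec.true_filters, geometry)
    values = percept.values

    if spec.jitter_amplitude_deg > 0:
        n = geometry.n_pixels
        amp_px = spec.jitter_amplitude_deg * geometry.pixels_per_degree
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        phases = rng.uniform(0, 2 * np.pi, size=4)
        cycles = rng.uniform(1.0, 2.5, size=2)  # 1-2.5 warp cycles across the field
        dx = amp_px * np.sin(2 * np.pi * cycles[0] * yy / n + phases[0]) \
            + amp_px * 0.5 * np.sin(2 * np.pi * cycles[1] * xx / n + phases[1])
        dy = amp_px * np.sin(2 * np.pi * cycles[0] * xx / n + phases[2]) \
            + amp_px * 0.5 * np.sin(2 * np.pi * cycles[1] * yy / n + phases[3])
        values = ndimage.map_coordinates(values, [yy + dy, xx + dx], order=1, mode="nearest")

    if spec.pixel_noise_sd > 0:
        values = values + rng.normal(0.0, spec.pixel_noise_sd, size=values.shape)

    values = np.clip(values, -1.0, 1.0)
    values = np.where(percept.aperture, values, 0.0)
    drawing = ImageField(values, geometry.extent_deg, geometry.pixels_per_degree,
                         percept.aperture)
    return drawing, spec.true_filters


def gen_csf_pair(
    fellow_params: Optional[dict] = None,
    amblyopic_params: Optional[dict] = None,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    sfs_cpd: Sequence[float] = STANDARD_SFS_CPD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sampled fellow/amblyopic CSF tables with multiplicative lognormal noise."""
    fellow_params = dict(FELLOW_CSF_PARAMS if fellow_params is None else fellow_params)
    amblyopic_params = dict(fellow_params if amblyopic_params is None else amblyopic_params)
    for p in (fellow_params, amblyopic_params):
        if min(p.values()) <= 0 and not (p["g0"] >= 0):
            raise ValueError("CSF parameters must be positive")
    rng = np.random.default_rng(rng_seed)
    sfs = np.asarray(sfs_cpd, dtype=float)

    def table(params: dict, eye: str) -> pd.DataFrame:
        sens = csf_value(sfs, params["g0"], params["g"], params["sf_p"], params["sigma"])
        if noise_sd > 0:
            sens = sens * np.exp(rng.normal(0.0, noise_sd, size=sens.shape))
        return pd.DataFrame({"eye": eye, "sf_cpd": sfs, "sensitivity": sens})

    return table(fellow_params, "fellow"), table(amblyopic_params, "amblyopic")


def gen_orientation_map(
    shape: tuple[int, int] = (228, 228),
    target_column_wavelength_mm: float = 0.79,
    mm_per_pixel: float = 3.3 / 228.0,
    rng_seed: int = 0,
) -> OrientationMap:
    """Orientation-preference map from band-pass-filtered complex white noise.

    Complex Gaussian noise is filtered with an annular Gaussian ring in the
    Fourier plane centered at 1/wavelength; the half-angle of the result
    gives orientations in [0, 180) with realistic pinwheel structure.
    Defaults approximate a macaque central-vision patch (3.3 x 3.3 mm,
    column width ~0.395 mm).
    """
    if target_column_wavelength_mm <= 2.0 * mm_per_pixel:
        raise ValueError("column wavelength below map resolution")
    rng = np.random.default_rng(rng_seed)
    ny, nx = shape
    noise = rng.normal(size=(ny, nx)) + 1j * rng.normal(size=(ny, nx))
    fy = np.fft.fftfreq(ny, d=mm_per_pixel)
    fx = np.fft.fftfreq(nx, d=mm_per_pixel)
    fr = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    f0 = 1.0 / target_column_wavelength_mm
    ring = np.exp(-((fr - f0) ** 2) / (2.0 * (f0 / 5.0) ** 2))
    z = np.fft.ifft2(np.fft.fft2(noise) * ring)
    orientations = (np.rad2deg(np.angle(z)) / 2.0) % 180.0
    return OrientationMap(orientations, mm_per_pixel, provenance="synthetic")


def default_battery() -> list[tuple[str, GratingParams, FilterSet]]:
    """Recovery battery: (name, stimulus params, truth filters), 1-4 filters.

    Orientations, spatial frequencies, phases, duty constants, saturation
    thresholds, and weights all vary across the battery so that every model
    parameter is exercised by the generated drawings.
    """
    battery = []
    stim1 = GratingParams(90.0, 5.0)
    battery.append((
        "one_filter",
        stim1,
        FilterSet([stim1.with_(duty_constant=-0.3, saturation_threshold=0.9)],
                  np.array([0.8])),
    ))
    stim2 = GratingParams(0.0, 5.0)
    battery.append((
        "two_filters",
        stim2,
        FilterSet(
            [
                stim2.with_(duty_constant=-0.3),
                GratingParams(30.0, 5.0, phase=120.0, duty_constant=-0.25),
            ],
            np.array([0.8, 0.3]),
        ),
    ))
    stim3 = GratingParams(0.0, 4.0)
    battery.append((
        "three_filters",
        stim3,
        FilterSet(
            [
                stim3.with_(duty_constant=0.25, saturation_threshold=1.1),
                GratingParams(60.0, 4.0, phase=45.0, duty_constant=-0.3),
                GratingParams(120.0, 5.0, phase=200.0, duty_constant=0.2),
            ],
            np.array([0.8, 0.35, 0.3]),
        ),
    ))
    stim4 = GratingParams(90.0, 5.0)
    battery.append((
        "four_filters",
        stim4,
        FilterSet(
            [
                stim4.with_(duty_constant=-0.35),
                GratingParams(45.0, 5.0, phase=90.0, duty_constant=-0.3),
                GratingParams(135.0, 4.0, phase=180.0, duty_constant=0.3),
                GratingParams(0.0, 6.0, phase=270.0, duty_constant=-0.2,
                              saturation_threshold=1.2),
            ],
            np.array([0.8, 0.35, 0.3, 0.3]),
        ),
    ))
    return battery


def _subject_filters(
    deficit: float,
    stim: GratingParams,
    rng: np.random.Generator,
    noise_sd: float,
) -> FilterSet:
    """Amblyopic filter set whose orientation mismatch, off-orientation weight
    and |K| all grow with the contrast-sensitivity deficit.

    The mismatch stays in the 8-20 degree range where the predicted cortical
    spread grows with mismatch (beyond ~25 degrees the Gaussian stimulus-
    similarity weight suppresses the filter's cortical contribution).
    """
    eps = rng.normal(0.0, noise_sd, size=4)
    k_mag = float(np.clip(0.08 + 0.18 * deficit + eps[0], 0.0, 0.65))
    w_off = float(np.clip(0.35 + 0.05 * deficit + eps[1], 0.05, 1.0))
    off_orientation = stim.orientation + 12.0 + 4.0 * deficit + 20.0 * eps[2]
    matched = GratingParams(
        orientation=stim.orientation,
        spatial_frequency=stim.spatial_frequency,
        phase=stim.phase,
        duty_constant=-k_mag,
        saturation_threshold=1.0,
    )
    off = GratingParams(
        orientation=off_orientation,
        spatial_frequency=float(np.clip(stim.spatial_frequency * (0.8 + 0.1 * eps[3]), 0.5, 16.0)),
        phase=float(rng.uniform(0, 360)),
        duty_constant=-k_mag,
        saturation_threshold=1.0,
    )
    return FilterSet([matched, off], np.array([0.8, w_off]))


def gen_cohort(spec: SyntheticCohortSpec) -> list[SyntheticSubject]:
    """Cohort with a built-in positive deficit-distortion link.

    Deficits span ``deficit_range``; each subject's amblyopic CSF peak is the
    fellow peak divided by (1 + deficit), and the drawing is generated from a
    filter set whose duty constants and off-orientation weight increase with
    the deficit, so the end-to-end deficit-distortion correlation is positive
    and recoverable.
    """
    lo, hi = spec.deficit_range
    deficits = np.linspace(lo + 0.1 * (hi - lo), hi, spec.n_subjects)
    subjects = []
    master = np.random.default_rng(spec.rng_seed)
    for i, deficit in enumerate(deficits):
        seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(seed)
        stim = GratingParams(
            orientation=0.0 if i % 2 == 0 else 90.0,
            spatial_frequency=5.0,
            phase=0.0,
        )
        truth = _subject_filters(float(deficit), stim, rng, spec.distortion_noise_sd)
        drawing, _ = gen_drawing(
            SyntheticDrawingSpec(true_filters=truth, rng_seed=seed), spec.geometry
        )
        fellow = dict(FELLOW_CSF_PARAMS)
        ambly = dict(fellow)
        # scale the peak (g0 + g) by 1/(1 + deficit), keeping the baseline share
        scale = 1.0 / (1.0 + float(deficit))
        ambly["g0"] = fellow["g0"] * scale
        ambly["g"] = fellow["g"] * scale
        csf_f, csf_a = gen_csf_pair(fellow, ambly, noise_sd=0.02, rng_seed=seed)
        subjects.append(
            SyntheticSubject(
                subject_id=f"S{i + 1}",
                deficit=float(deficit),
                stimulus_params=stim,
                stimulus=make_grating(stim, spec.geometry),
                drawing=drawing,
                truth=truth,
                csf_fellow=csf_f,
                csf_amblyopic=csf_a,
                rng_seed=seed,
            )
        )
    return subjects
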