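"""LGN spatial-frequency tuning and receptive-field mapping.

Tuning curves (mean firing rate vs grating spatial frequency, measured at
several contrasts) are summarized with Gaussian fits; the low/high
spatial-frequency split quantifies how much a contrast reduction suppresses
responses below vs above 0.2 cpd.  Spatiotemporal receptive fields are
estimated by reverse correlation (spike-triggered averaging) of a binary
checkerboard movie.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "TuningCurve",
    "TuningFit",
    "SpatioTemporalRF",
    "fit_tuning",
    "lsf_hsf_difference",
    "reverse_correlate",
]


@dataclass
class TuningCurve:
    """Mean firing rates per spatial frequency at one stimulus contrast."""

    spatial_frequencies: np.ndarray  # cpd, strictly increasing
    mean_rates: np.ndarray  # spikes/s
    contrast: float = 98.0  # percent
    n_trials: int = 10

    def __post_init__(self) -> None:
        self.spatial_frequencies = np.asarray(self.spatial_frequencies, dtype=float)
        self.mean_rates = np.asarray(self.mean_rates, dtype=float)
        if self.spatial_frequencies.shape != self.mean_rates.shape:
            raise ValueError("frequency and rate arrays must match")
        if np.any(np.diff(self.spatial_frequencies) <= 0):
            raise ValueError("spatial frequencies must be strictly increasing")
        if np.any(self.mean_rates < 0):
            raise ValueError("rates must be >= 0")


@dataclass
class TuningFit:
    baseline: float
    gain: float
    preferred_sf: float
    width: float
    r_squared: float
    converged: bool
    included: bool  # population filter: R^2 > 0.9

    def __call__(self, sf):
        return _gauss(np.asarray(sf, dtype=float), self.baseline, self.gain,
                      self.preferred_sf, self.width)


@dataclass
class SpatioTemporalRF:
    """Normalized spike-triggered average volume (y, x, time-lag)."""

    volume: np.ndarray
    check_size_deg: float = 0.9
    frame_ms: float = 15.5
    lag_step_ms: float = 15.0
    polarity: str = "ON"

    @property
    def n_lags(self) -> int:
        return self.volume.shape[-1]


def _gauss(sf, baseline, gain, preferred_sf, width):
    return baseline + gain * np.exp(-((sf - preferred_sf) ** 2) / (2.0 * width**2))


def fit_tuning(curve: TuningCurve, r2_inclusion: float = 0.9) -> TuningFit:
    """Gaussian fit of one tuning curve; flags R^2-based population inclusion."""
    sf = curve.spatial_frequencies
    rates = curve.mean_rates
    if sf.size < 5:
        raise ValueError("need at least 5 spatial-frequency points")
    if np.ptp(rates) < 1e-12:
        return TuningFit(float(rates.mean()), 0.0, float(sf.mean()), np.nan,
                         r_squared=np.nan, converged=False, included=False)
    p0 = [max(rates.min(), 0.0), np.ptp(rates), sf[np.argmax(rates)], np.ptp(sf) / 4.0]
    try:
        popt, _ = optimize.curve_fit(
            _gauss, sf, rates, p0=p0,
            bounds=([0.0, 0.0, 1e-4, 1e-4], [np.inf, np.inf, 10.0 * sf.max(), np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return TuningFit(*p0, r_squared=np.nan, converged=False, included=False)  # type: ignore[arg-type]
    pred = _gauss(sf, *popt)
    ss_tot = float(np.sum((rates - rates.mean()) ** 2))
    r2 = 1.0 - float(np.sum((rates - pred) ** 2)) / ss_tot if ss_tot > 0 else np.nan
    return TuningFit(*map(float, popt), r_squared=r2, converged=True,
                     included=bool(r2 > r2_inclusion))


def lsf_hsf_difference(
    high: TuningCurve, low: TuningCurve, split_cpd: float = 0.2
) -> tuple[float, float]:
    """Mean high-minus-low contrast rate difference below/above the SF split.

    Returns (lsf_diff, hsf_diff): averages of (rate_high - rate_low) over
    spatial frequencies <= split_cpd and > split_cpd respectively.
    """
    if not np.allclose(high.spatial_frequencies, low.spatial_frequencies):
        raise ValueError("tuning curves must share the spatial-frequency grid")
    sf = high.spatial_frequencies
    diff = high.mean_rates - low.mean_rates
    lsf = diff[sf <= split_cpd]
    hsf = diff[sf > split_cpd]
    if lsf.size == 0 or hsf.size == 0:
        raise ValueError(f"no spatial frequencies on one side of {split_cpd} cpd")
    return float(lsf.mean()), float(hsf.mean())


def reverse_correlate(
    spike_times_ms: Sequence[float],
    stimulus_movie: np.ndarray,
    frame_ms: float = 15.5,
    n_lags: int = 19,
    lag_step_ms: float = 15.0,
    spike_weights: Optional[Sequence[float]] = None,
    interpolation_factor: int = 3,
) -> SpatioTemporalRF:
    """Spatiotemporal receptive field by spike-triggered averaging.

    ``stimulus_movie`` is (n_frames, ny, nx); binary {0, 1} frames are
    recoded to +-1 contrast.  For each lag the average stimulus frame
    preceding the spikes by lag*lag_step_ms is accumulated; the volume is
    normalized (mean subtracted, peak |value| scaled to 1) and spatially
    interpolated by ``interpolation_factor``.  Polarity is the sign of the
    largest-magnitude value: ON for positive (light-driven), OFF otherwise.
    """
    spikes = np.asarray(spike_times_ms, dtype=float)
    if spikes.size == 0:
        raise ValueError("no spikes")
    movie = np.asarray(stimulus_movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("stimulus_movie must be (n_frames, ny, nx)")
    if movie.min() >= 0.0 and movie.max() <= 1.0:
        movie = 2.0 * movie - 1.0
    n_frames, ny, nx = movie.shape
    duration = n_frames * frame_ms
    if np.any(spikes < 0) or np.any(spikes >= duration):
        raise ValueError("spikes must lie within the movie duration")
    weights = np.ones_like(spikes) if spike_weights is None else np.asarray(spike_weights, float)

    sta = np.zeros((ny, nx, n_lags))
    for lag in range(n_lags):
        t = spikes - lag * lag_step_ms
        valid = t >= 0
        if not np.any(valid):
            continue
        idx = np.floor(t[valid] / frame_ms).astype(int)
        w = weights[valid]
        sta[:, :, lag] = np.tensordot(w, movie[idx], axes=(0, 0)) / w.sum()

    sta -= sta.mean()
    peak = np.abs(sta).max()
    if peak > 0:
        sta /= peak
    polarity = "ON" if sta.flat[np.argmax(np.abs(sta))] > 0 else "OFF"
    if interpolation_factor > 1:
        sta = ndimage.zoom(sta, (interpolation_factor, interpolation_factor, 1), order=3)
        peak = np.abs(sta).max()
        if peak > 0:
            sta /= peak  # keep the max-|value| = 1 contract after smoothing
    return SpatioTemporalRF(volume=sta, frame_ms=frame_ms, lag_step_ms=lag_step_ms,
                            polarity=polarity)
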