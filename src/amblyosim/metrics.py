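"""Distortion magnitude, contrast-sensitivity deficits, and cohort statistics.

Distortion magnitude summarizes a subject's fitted filter sets: for stimuli of
at least 3 cpd, filters are split into orientation-matched (|O_S - O_G| <= 5
deg, circular) and not-matched classes; the score is the absolute difference
of the class-mean weights times the mean |K| duty constant, optionally
normalized by the cohort maximum.  Contrast sensitivity per eye is a Gaussian
in spatial frequency, and the deficit is the fellow/amblyopic ratio of fitted
peaks minus one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .fitting import FitResult

__all__ = [
    "CSFModel",
    "DistortionScore",
    "distortion_magnitude",
    "fit_csf",
    "csf_value",
    "cs_deficit",
    "bootstrap_sf_distribution",
    "correlate",
    "rank_sum_test",
    "binomial_test",
]


@dataclass
class CSFModel:
    """Gaussian contrast-sensitivity model CS(sf) = g0 + g*exp(-(sf-sf_p)^2/(2*sigma^2))."""

    g0: float
    g: float
    sf_p: float
    sigma: float
    converged: bool = True
    r_squared: float = float("nan")
    eye: str = ""

    @property
    def peak(self) -> float:
        """Fitted maximum sensitivity, the value g0 + g attained at sf_p."""
        return self.g0 + self.g

    def __call__(self, sf: np.ndarray | float) -> np.ndarray | float:
        return csf_value(np.asarray(sf, dtype=float), self.g0, self.g, self.sf_p, self.sigma)


@dataclass
class DistortionScore:
    raw: float
    normalized: float
    n_stimuli_used: int
    matched_mean: float
    notmatched_mean: float
    duty_mean: float


def _circ_orient_diff(a: float, b: float) -> float:
    """Absolute orientation difference on the 180-degree circle, in [0, 90]."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def distortion_magnitude(
    fits: Sequence[FitResult],
    cohort_raw: Optional[Iterable[float]] = None,
    sf_min_cpd: float = 3.0,
    match_tolerance_deg: float = 5.0,
    use_absolute_difference: bool = True,
) -> DistortionScore:
    """Distortion score |Wn - Wm| * mean(|K|) over stimuli with SF >= 3 cpd.

    ``cohort_raw`` supplies all subjects' raw scores for [0, 1] normalization;
    without it a positive raw score normalizes to 1 (single-subject use).
    Each fit must carry its stimulus parameters.
    """
    matched_w: list[float] = []
    notmatched_w: list[float] = []
    abs_k: list[float] = []
    n_used = 0
    for fit in fits:
        if fit.stimulus is None:
            raise ValueError("FitResult lacks stimulus parameters")
        if fit.stimulus.spatial_frequency < sf_min_cpd:
            continue
        n_used += 1
        o_s = fit.stimulus.orientation
        for p, w in zip(fit.filter_set.filters, fit.filter_set.weights):
            if w == 0:  # a zero-weight filter does not shape the percept
                continue
            diff = _circ_orient_diff(o_s, p.orientation)
            (matched_w if diff <= match_tolerance_deg else notmatched_w).append(float(w))
            abs_k.append(abs(p.duty_constant))
    if n_used == 0:
        raise ValueError(f"no stimuli with spatial frequency >= {sf_min_cpd} cpd")

    wm = float(np.mean(matched_w)) if matched_w else 0.0
    wn = float(np.mean(notmatched_w)) if notmatched_w else 0.0
    k_bar = float(np.mean(abs_k)) if abs_k else 0.0
    diff = wn - wm
    raw = (abs(diff) if use_absolute_difference else diff) * k_bar

    if cohort_raw is not None:
        cohort_max = max(abs(r) for r in cohort_raw)
        normalized = raw / cohort_max if cohort_max > 0 else 0.0
    else:
        normalized = 1.0 if raw > 0 else 0.0
    return DistortionScore(
        raw=raw,
        normalized=float(normalized),
        n_stimuli_used=n_used,
        matched_mean=wm,
        notmatched_mean=wn,
        duty_mean=k_bar,
    )


def csf_value(sf, g0, g, sf_p, sigma):
    return g0 + g * np.exp(-((sf - sf_p) ** 2) / (2.0 * sigma**2))


def fit_csf(sf: Sequence[float], sensitivity: Sequence[float], eye: str = "") -> CSFModel:
    """Least-squares Gaussian fit to a (spatial frequency, sensitivity) table."""
    sf = np.asarray(sf, dtype=float)
    sens = np.asarray(sensitivity, dtype=float)
    if sf.size < 4:
        raise ValueError("need at least 4 measurement points")
    if np.any(sf <= 0):
        raise ValueError("spatial frequencies must be > 0")
    if np.ptp(sens) < 1e-12:  # flat: sigma/sf_p unidentifiable
        return CSFModel(float(sens.mean()), 0.0, float(sf.mean()), np.nan,
                        converged=False, eye=eye)
    p0 = [max(sens.min(), 0.0), np.ptp(sens), sf[np.argmax(sens)], np.ptp(sf) / 2.0]
    try:
        popt, _ = optimize.curve_fit(
            csf_value, sf, sens, p0=p0,
            bounds=([0.0, 0.0, 1e-3, 1e-3], [np.inf, np.inf, 10.0 * sf.max(), np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return CSFModel(*p0, converged=False, eye=eye)  # type: ignore[arg-type]
    pred = csf_value(sf, *popt)
    ss_res = float(np.sum((sens - pred) ** 2))
    ss_tot = float(np.sum((sens - sens.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return CSFModel(*map(float, popt), converged=True, r_squared=r2, eye=eye)


def cs_deficit(fellow: CSFModel, amblyopic: CSFModel, floor_at_zero: bool = True) -> float:
    """Contrast-sensitivity deficit: fellow/amblyopic peak ratio minus one."""
    if not (fellow.converged and amblyopic.converged):
        raise ValueError("both CSF fits must have converged")
    if amblyopic.peak <= 0:
        raise ValueError("amblyopic peak must be positive")
    deficit = fellow.peak / amblyopic.peak - 1.0
    return max(0.0, deficit) if floor_at_zero else deficit


def bootstrap_sf_distribution(
    frequencies: Sequence[float],
    n_boot: int = 1000,
    n_per_sample: int = 30,
    noise_half_range_cpd: float = 2.0,
    n_bins: int = 9,
    rng_seed: int = 0,
    bin_range: Optional[tuple[float, float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean bootstrap spatial-frequency distribution (probabilities, bin edges).

    Each of ``n_boot`` samples draws ``n_per_sample`` frequencies with
    replacement, smooths them with uniform noise in +-noise_half_range, and
    bins into ``n_bins`` bins; the per-sample histograms are normalized and
    averaged.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency list")
    rng = np.random.default_rng(rng_seed)
    if bin_range is None:
        bin_range = (freqs.min() - noise_half_range_cpd, freqs.max() + noise_half_range_cpd)
    edges = np.linspace(bin_range[0], bin_range[1], n_bins + 1)
    acc = np.zeros(n_bins)
    for _ in range(n_boot):
        draw = rng.choice(freqs, size=n_per_sample, replace=True)
        draw = draw + rng.uniform(-noise_half_range_cpd, noise_half_range_cpd, size=n_per_sample)
        hist, _ = np.histogram(np.clip(draw, edges[0], edges[-1]), bins=edges)
        acc += hist / n_per_sample
    return acc / n_boot, edges


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation coefficient and two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("inputs must have nonzero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Wilcoxon rank-sum test (statistic, p)."""
    res = stats.ranksums(a, b)
    return float(res.statistic), float(res.pvalue)


def binomial_test(k: int, n: int, p: float = 0.5) -> float:
    """Two-sided binomial test p value (e.g., ON vs OFF dominance counts)."""
    return float(stats.binomtest(k, n, p).pvalue)
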