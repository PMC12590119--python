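"""Normalized Laplacian pyramid distance (NLPD).

Perceptual image dissimilarity computed in a Laplacian pyramid domain whose
band-pass coefficients are divisively normalized by a local average of
coefficient magnitudes — a light-weight model of retinal/cortical gain
control.  The distance is the root-mean-square difference of normalized
coefficients per scale, averaged over scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .percept import ImageField

__all__ = [
    "NLPDParams",
    "PyramidRepresentation",
    "build_normalized_pyramid",
    "nlpd",
    "nlpd_from_pyramid",
]

_BINOM5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass
class NLPDParams:
    """Tunable pieces of the pyramid and its divisive normalization.

    n_scales
        Pyramid depth; ``None`` selects floor(log2(side)) - 2 (6 for 256x256).
    lowpass_kernel
        1-D separable blur used for downsampling/upsampling (sums to 1).
    normalization_constant
        Stabilizer added to the local magnitude average (> 0).
    normalization_filter
        2-D weights for the local magnitude average (uniform 3x3 default).
    """

    n_scales: Optional[int] = None
    lowpass_kernel: np.ndarray = field(default_factory=lambda: _BINOM5.copy())
    normalization_constant: float = 0.17
    normalization_filter: np.ndarray = field(default_factory=lambda: np.full((3, 3), 1.0 / 9.0))

    def __post_init__(self) -> None:
        self.lowpass_kernel = np.asarray(self.lowpass_kernel, dtype=float)
        self.normalization_filter = np.asarray(self.normalization_filter, dtype=float)
        if not np.isclose(self.lowpass_kernel.sum(), 1.0):
            raise ValueError("lowpass kernel must sum to 1")
        if self.normalization_constant <= 0:
            raise ValueError("normalization_constant must be > 0")

    def depth_for(self, side: int) -> int:
        if self.n_scales is not None:
            return int(self.n_scales)
        return max(1, int(np.floor(np.log2(side))) - 2)


@dataclass
class PyramidRepresentation:
    """Ordered normalized band-pass scales y(k) of one image."""

    scales: list[np.ndarray]

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    @property
    def elements_per_scale(self) -> list[int]:
        return [s.size for s in self.scales]


def _blur(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    out = ndimage.correlate1d(img, kernel, axis=0, mode="reflect")
    return ndimage.correlate1d(out, kernel, axis=1, mode="reflect")


def _downsample(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return _blur(img, kernel)[::2, ::2]


def _upsample(img: np.ndarray, shape: tuple[int, int], kernel: np.ndarray) -> np.ndarray:
    # pad the small image before zero interleaving: reflecting the
    # interleaved grid directly would break sample parity at the border and
    # leak boundary artifacts into every band
    pad = 2
    padded = np.pad(img, pad, mode="symmetric")
    up = np.zeros((2 * padded.shape[0], 2 * padded.shape[1]))
    up[::2, ::2] = padded
    # factor 4 restores unit DC gain after zero interleaving in 2-D
    blurred = _blur(up, 2.0 * kernel)
    return blurred[2 * pad : 2 * pad + shape[0], 2 * pad : 2 * pad + shape[1]]


def laplacian_pyramid(img: np.ndarray, params: NLPDParams) -> list[np.ndarray]:
    """Unnormalized Laplacian pyramid; last scale is the low-pass residual."""
    side = min(img.shape)
    depth = params.depth_for(side)
    if side < 2**depth:
        raise ValueError(f"image side {side} too small for {depth} scales")
    scales: list[np.ndarray] = []
    current = np.asarray(img, dtype=float)
    if depth == 1:
        # single-scale pyramid: one band-pass (image minus its blur)
        low = _downsample(current, params.lowpass_kernel)
        return [current - _upsample(low, current.shape, params.lowpass_kernel)]
    for _ in range(depth - 1):
        low = _downsample(current, params.lowpass_kernel)
        scales.append(current - _upsample(low, current.shape, params.lowpass_kernel))
        current = low
    scales.append(current)
    return scales


def collapse_pyramid(scales: list[np.ndarray], params: NLPDParams) -> np.ndarray:
    """Invert :func:`laplacian_pyramid` (exact reconstruction)."""
    current = scales[-1]
    for band in reversed(scales[:-1]):
        current = band + _upsample(current, band.shape, params.lowpass_kernel)
    return current


def _normalize(band: np.ndarray, params: NLPDParams) -> np.ndarray:
    local = ndimage.correlate(np.abs(band), params.normalization_filter, mode="reflect")
    return band / (params.normalization_constant + local)


def build_normalized_pyramid(img: ImageField | np.ndarray, params: NLPDParams | None = None) -> PyramidRepresentation:
    """Laplacian pyramid followed by divisive normalization of every scale."""
    if params is None:
        params = NLPDParams()
    values = img.values if isinstance(img, ImageField) else np.asarray(img, dtype=float)
    bands = laplacian_pyramid(values, params)
    return PyramidRepresentation([_normalize(b, params) for b in bands])


def nlpd_from_pyramid(pyr_a: PyramidRepresentation, pyr_b: PyramidRepresentation) -> float:
    """Distance between two prebuilt representations (fit-loop fast path)."""
    if pyr_a.n_scales != pyr_b.n_scales:
        raise ValueError("pyramids have different depths")
    dists = [
        np.sqrt(np.mean((ya - yb) ** 2))
        for ya, yb in zip(pyr_a.scales, pyr_b.scales)
    ]
    return float(np.mean(dists))


def nlpd(a: ImageField | np.ndarray, b: ImageField | np.ndarray, params: NLPDParams | None = None) -> float:
    """NLPD(a, b): mean over scales of the RMS normalized-coefficient difference.

    Symmetric, non-negative, and zero iff the normalized representations
    coincide.
    """
    if params is None:
        params = NLPDParams()
    if isinstance(a, ImageField) and isinstance(b, ImageField) and not a.same_geometry(b):
        raise ValueError("images must share geometry")
    va = a.values if isinstance(a, ImageField) else np.asarray(a, dtype=float)
    vb = b.values if isinstance(b, ImageField) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError("images must share shape")
    return nlpd_from_pyramid(
        build_normalized_pyramid(va, params), build_normalized_pyramid(vb, params)
    )
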