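"""Independent, deliberately naive NLPD oracle.

Implements the same pyramid/normalization/distance definitions as the
package, but with explicit Python loops and index arithmetic instead of
scipy.ndimage — an independent code path used to bound the implementation's
numerical behaviour.  Only suitable for small images.
"""

import math

import numpy as np

BINOM5 = [1 / 16, 4 / 16, 6 / 16, 4 / 16, 1 / 16]


def _reflect(i: int, n: int) -> int:
    # scipy.ndimage "reflect" boundary: (d c b a | a b c d)
    while i < 0 or i >= n:
        if i < 0:
            i = -i - 1
        else:
            i = 2 * n - i - 1
    return i


def blur(img):
    ny, nx = img.shape
    tmp = np.zeros_like(img)
    for y in range(ny):
        for x in range(nx):
            acc = 0.0
            for k in range(-2, 3):
                acc += BINOM5[k + 2] * img[_reflect(y + k, ny), x]
            tmp[y, x] = acc
    out = np.zeros_like(img)
    for y in range(ny):
        for x in range(nx):
            acc = 0.0
            for k in range(-2, 3):
                acc += BINOM5[k + 2] * tmp[y, _reflect(x + k, nx)]
            out[y, x] = acc
    return out


def blur2(img):
    """Blur with the doubled kernel (upsampling interpolation)."""
    ny, nx = img.shape
    tmp = np.zeros_like(img)
    for y in range(ny):
        for x in range(nx):
            acc = 0.0
            for k in range(-2, 3):
                acc += 2.0 * BINOM5[k + 2] * img[_reflect(y + k, ny), x]
            tmp[y, x] = acc
    out = np.zeros_like(img)
    for y in range(ny):
        for x in range(nx):
            acc = 0.0
            for k in range(-2, 3):
                acc += 2.0 * BINOM5[k + 2] * tmp[y, _reflect(x + k, nx)]
            out[y, x] = acc
    return out


def downsample(img):
    return blur(img)[::2, ::2]


def upsample(img, shape):
    pad = 2
    ny, nx = img.shape
    padded = np.zeros((ny + 2 * pad, nx + 2 * pad))
    for y in range(ny + 2 * pad):
        for x in range(nx + 2 * pad):
            padded[y, x] = img[_reflect(y - pad, ny), _reflect(x - pad, nx)]
    up = np.zeros((2 * padded.shape[0], 2 * padded.shape[1]))
    up[::2, ::2] = padded
    out = blur2(up)
    return out[2 * pad : 2 * pad + shape[0], 2 * pad : 2 * pad + shape[1]]


def pyramid(img, depth):
    scales = []
    current = img.astype(float)
    if depth == 1:
        return [current - upsample(downsample(current), current.shape)]
    for _ in range(depth - 1):
        low = downsample(current)
        scales.append(current - upsample(low, current.shape))
        current = low
    scales.append(current)
    return scales


def normalize(band, constant=0.17):
    ny, nx = band.shape
    out = np.zeros_like(band)
    for y in range(ny):
        for x in range(nx):
            acc = 0.0
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    acc += abs(band[_reflect(y + dy, ny), _reflect(x + dx, nx)]) / 9.0
            out[y, x] = band[y, x] / (constant + acc)
    return out


def naive_nlpd(a, b, depth=None):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if depth is None:
        depth = max(1, int(math.floor(math.log2(min(a.shape)))) - 2)
    ya = [normalize(s) for s in pyramid(a, depth)]
    yb = [normalize(s) for s in pyramid(b, depth)]
    dists = []
    for sa, sb in zip(ya, yb):
        acc = 0.0
        for y in range(sa.shape[0]):
            for x in range(sa.shape[1]):
                acc += (sa[y, x] - sb[y, x]) ** 2
        dists.append(math.sqrt(acc / sa.size))
    return sum(dists) / len(dists)
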