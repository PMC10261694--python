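"""Independent brute-force reference implementations used only by the tests.

These deliberately use naive double loops and textbook formulas so they share
no code path with the package implementations they check.
"""

import math

import numpy as np


def nlm_bruteforce(img: np.ndarray, patch: int, search: int, h: float,
                   self_weight_rule: str = "self") -> np.ndarray:
    """O(n^2 * search^2 * patch^2) non-local means with uniform patch
    weighting and a single mirror ('reflect') pad of the slice."""
    p_half, s_half = patch // 2, search // 2
    pad = s_half + p_half
    P = np.pad(np.asarray(img, dtype=np.float64), pad, mode="reflect")
    H, W = img.shape
    out = np.zeros((H, W))
    norm = patch * patch
    for i in range(H):
        for j in range(W):
            ci, cj = i + pad, j + pad
            num = den = 0.0
            wmax = 0.0
            for dy in range(-s_half, s_half + 1):
                for dx in range(-s_half, s_half + 1):
                    if dy == 0 and dx == 0:
                        continue
                    d2 = 0.0
                    for u in range(-p_half, p_half + 1):
                        for v in range(-p_half, p_half + 1):
                            diff = P[ci + u, cj + v] - P[ci + dy + u, cj + dx + v]
                            d2 += diff * diff
                    w = math.exp(-(d2 / norm) / (h * h))
                    num += w * P[ci + dy, cj + dx]
                    den += w
                    wmax = max(wmax, w)
            w_self = 1.0 if self_weight_rule == "self" else wmax
            num += w_self * P[ci, cj]
            den += w_self
            out[i, j] = num / den
    return out


def box_mean_bruteforce(img: np.ndarray, search: int, patch: int) -> np.ndarray:
    """Unweighted mean of the search window around each pixel, using the same
    single mirror pad as the NLM implementation."""
    s_half, p_half = search // 2, patch // 2
    pad = s_half + p_half
    P = np.pad(np.asarray(img, dtype=np.float64), pad, mode="reflect")
    H, W = img.shape
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            ci, cj = i + pad, j + pad
            out[i, j] = P[ci - s_half:ci + s_half + 1,
                          cj - s_half:cj + s_half + 1].mean()
    return out


def gaussian_kernel_1d(sigma: float, radius: int) -> np.ndarray:
    """Sampled Gaussian normalized to unit sum."""
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def mean_sd(values) -> tuple[float, float]:
    """Textbook sample statistics computed with explicit sums."""
    xs = [float(v) for v in values]
    n = len(xs)
    mean = sum(xs) / n
    var = sum((x - mean) ** 2 for x in xs) / (n - 1)
    return mean, math.sqrt(var)


def mean_sd_cv(values) -> tuple[float, float, float]:
    mean, sd = mean_sd(values)
    return mean, sd, sd / mean * 100.0


def bland_altman_bruteforce(ds) -> tuple[float, float]:
    mean, sd = mean_sd(ds)
    return mean, 1.96 * sd


def suv_max_peak_bruteforce(values: np.ndarray, voi: np.ndarray,
                            voxel_mm: float, peak_diameter_mm: float = 10.0):
    """Maximum over the VOI (lowest coordinate on ties) and the mean over
    pixels whose centres fall within the peak radius on the max slice."""
    best = None
    nz, nr, nc = values.shape
    for z in range(nz):
        for r in range(nr):
            for c in range(nc):
                if voi[z, r, c]:
                    v = values[z, r, c]
                    if best is None or v > best[0]:
                        best = (v, (z, r, c))
    suv_max, (z0, r0, c0) = best
    rad = peak_diameter_mm / 2.0 / voxel_mm
    members = []
    for r in range(nr):
        for c in range(nc):
            if (r - r0) ** 2 + (c - c0) ** 2 <= rad * rad:
                members.append(values[z0, r, c])
    return suv_max, sum(members) / len(members), (z0, r0, c0)
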