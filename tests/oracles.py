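"""Independent, deliberately naive reference implementations.

Each oracle recomputes a quantity by the most literal route available —
direct O(N^4) DFT sums, exhaustive candidate scans, per-pixel straight-line
conversions — sharing no code with the package's fast paths.  They exist
only to pin expected values in tests.
"""

from __future__ import annotations

import colorsys
import math

import numpy as np

# ---------------------------------------------------------------------------
# spectral residual, transcribed step by step with a direct DFT


def naive_dft2(img: np.ndarray) -> np.ndarray:
    """Unnormalized forward 2-D DFT by explicit summation."""
    img = np.asarray(img, dtype=np.complex128)
    m, n = img.shape
    out = np.zeros((m, n), dtype=np.complex128)
    ys = np.arange(m)
    xs = np.arange(n)
    for u in range(m):
        row_phase = np.exp(-2j * np.pi * u * ys / m)
        for v in range(n):
            col_phase = np.exp(-2j * np.pi * v * xs / n)
            out[u, v] = np.sum(img * np.outer(row_phase, col_phase))
    return out


def naive_idft2(spec: np.ndarray) -> np.ndarray:
    """Inverse 2-D DFT (1/MN normalization) by explicit summation."""
    spec = np.asarray(spec, dtype=np.complex128)
    m, n = spec.shape
    out = np.zeros((m, n), dtype=np.complex128)
    us = np.arange(m)
    vs = np.arange(n)
    for y in range(m):
        row_phase = np.exp(2j * np.pi * y * us / m)
        for x in range(n):
            col_phase = np.exp(2j * np.pi * x * vs / n)
            out[y, x] = np.sum(spec * np.outer(row_phase, col_phase)) / (m * n)
    return out


def naive_uniform_filter(img: np.ndarray, size: int) -> np.ndarray:
    """Mean filter with replicate (edge) border handling."""
    r = size // 2
    padded = np.pad(img, r, mode="edge")
    out = np.empty_like(np.asarray(img, dtype=np.float64))
    m, n = img.shape
    for y in range(m):
        for x in range(n):
            out[y, x] = padded[y : y + size, x : x + size].mean()
    return out


def naive_gaussian_filter(img: np.ndarray, sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Separable Gaussian with symmetric (reflect) border, sampled kernel."""
    radius = int(truncate * sigma + 0.5)
    xs = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (xs / sigma) ** 2)
    kernel /= kernel.sum()

    def conv_axis(a: np.ndarray, axis: int) -> np.ndarray:
        a = np.moveaxis(a, axis, 0)
        padded = np.pad(a, ((radius, radius),) + ((0, 0),) * (a.ndim - 1), mode="symmetric")
        out = np.zeros_like(a, dtype=np.float64)
        for i, w in enumerate(kernel):
            out += w * padded[i : i + a.shape[0]]
        return np.moveaxis(out, 0, axis)

    return conv_axis(conv_axis(np.asarray(img, dtype=np.float64), 0), 1)


def naive_spectral_residual(
    gray: np.ndarray,
    avg_filter_size: int = 3,
    gauss_sigma: float = 0.8,
    log_epsilon: float = 1e-8,
) -> np.ndarray:
    """Literal transcription of the saliency transform around a naive DFT."""
    gray = np.asarray(gray, dtype=np.float64)
    spectrum = naive_dft2(gray)
    amplitude = np.abs(spectrum)
    phase = np.angle(spectrum)
    log_amp = np.log(amplitude + log_epsilon)
    residual = log_amp - naive_uniform_filter(log_amp, avg_filter_size)
    recon = naive_idft2(np.exp(residual + 1j * phase))
    return naive_gaussian_filter(np.abs(recon) ** 2, gauss_sigma)


# ---------------------------------------------------------------------------
# exhaustive threshold scans


def exhaustive_otsu(plane: np.ndarray) -> int:
    """Best threshold by looping all 255 splits of the 256-bin histogram."""
    values = np.clip(np.round(np.asarray(plane, dtype=np.float64)), 0, 255).astype(int)
    hist = [0] * 256
    for v in values.ravel():
        hist[v] += 1
    total = sum(hist)
    best_t, best_sigma = None, -1.0
    for t in range(255):
        w0 = sum(hist[: t + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(i * hist[i] for i in range(t + 1)) / w0
        mu1 = sum(i * hist[i] for i in range(t + 1, 256)) / w1
        sigma = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if sigma > best_sigma:
            best_sigma, best_t = sigma, t
    return best_t


def random_unimodal_histogram(rng, bins: int = 256) -> np.ndarray:
    """Dark-peaked decaying histogram with a noisy bright tail."""
    peak = int(rng.integers(0, 12))
    scale = rng.uniform(5, 40)
    b = np.arange(bins, dtype=float)
    counts = 1000.0 * np.exp(-np.clip(b - peak, 0, None) / scale)
    counts[:peak] = counts[peak] * rng.uniform(0.1, 0.9, peak)
    tail_len = int(rng.integers(10, 200))
    counts[bins - tail_len :] += rng.uniform(0, 3, tail_len)
    return np.round(counts)


def exhaustive_triangle_bin(counts: np.ndarray) -> int:
    """Max perpendicular-distance bin by scanning every candidate."""
    counts = np.asarray(counts, dtype=float)
    n = counts.size
    peak = int(np.argmax(counts))
    end = max(i for i in range(n) if counts[i] > 0)
    xp, yp = peak / (n - 1), counts[peak] / counts.max()
    xe, ye = end / (n - 1), counts[end] / counts.max()
    dx, dy = xe - xp, ye - yp
    norm = math.hypot(dx, dy)
    best_bin, best_d = peak, -1.0
    for b in range(peak, end + 1):
        xb, yb = b / (n - 1), counts[b] / counts.max()
        d = abs(dy * (xb - xp) - dx * (yb - yp)) / norm
        if d > best_d:  # strict: ties keep the lowest bin
            best_d, best_bin = d, b
    return best_bin


# ---------------------------------------------------------------------------
# per-pixel color conversion + averaging

# scikit-image's published sRGB -> XYZ matrix and D65/2 white point, restated
# here so the conversion is an independent straight-line computation
_XYZ_FROM_RGB = [
    [0.412453, 0.357580, 0.180423],
    [0.212671, 0.715160, 0.072169],
    [0.019334, 0.119193, 0.950227],
]
_D65_WHITE = (0.95047, 1.0, 1.08883)


def _srgb_to_linear(c: float) -> float:
    return c / 12.92 if c <= 0.04045 else ((c + 0.055) / 1.055) ** 2.4


def _lab_f(t: float) -> float:
    eps = 0.008856  # (6/29)^3 as used classically
    return t ** (1 / 3) if t > eps else 7.787 * t + 16.0 / 116.0


def pixel_to_lab(r: float, g: float, b: float) -> tuple[float, float, float]:
    rl, gl, bl = (_srgb_to_linear(c / 255.0) for c in (r, g, b))
    x = _XYZ_FROM_RGB[0][0] * rl + _XYZ_FROM_RGB[0][1] * gl + _XYZ_FROM_RGB[0][2] * bl
    y = _XYZ_FROM_RGB[1][0] * rl + _XYZ_FROM_RGB[1][1] * gl + _XYZ_FROM_RGB[1][2] * bl
    z = _XYZ_FROM_RGB[2][0] * rl + _XYZ_FROM_RGB[2][1] * gl + _XYZ_FROM_RGB[2][2] * bl
    fx, fy, fz = (
        _lab_f(x / _D65_WHITE[0]),
        _lab_f(y / _D65_WHITE[1]),
        _lab_f(z / _D65_WHITE[2]),
    )
    ell = 116.0 * fy - 16.0
    return (ell, 500.0 * (fx - fy), 200.0 * (fy - fz))


def pixel_to_hsv(r: float, g: float, b: float) -> tuple[float, float, float]:
    h, s, v = colorsys.rgb_to_hsv(r / 255.0, g / 255.0, b / 255.0)
    return (h * 360.0) % 360.0, s, v


def pixel_to_ycbcr(r: float, g: float, b: float) -> tuple[float, float, float]:
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    return y, cb, cr


def straight_line_mean_color(pixels: np.ndarray, space: str) -> tuple[float, float, float]:
    """Per-pixel convert-then-average, one pixel at a time."""
    converted = []
    for r, g, b in np.asarray(pixels, dtype=float):
        if space == "RGB":
            converted.append((r, g, b))
        elif space == "HSV":
            converted.append(pixel_to_hsv(r, g, b))
        elif space == "YCbCr":
            converted.append(pixel_to_ycbcr(r, g, b))
        elif space == "LAB":
            converted.append(pixel_to_lab(r, g, b))
        else:
            raise ValueError(space)
    n = len(converted)
    means = [sum(c[i] for c in converted) / n for i in range(3)]
    if space == "HSV":
        sin_sum = sum(math.sin(math.radians(c[0])) for c in converted)
        cos_sum = sum(math.cos(math.radians(c[0])) for c in converted)
        means[0] = math.degrees(math.atan2(sin_sum / n, cos_sum / n)) % 360.0
    return tuple(means)


# ---------------------------------------------------------------------------
# assignment and regression


def brute_force_min_cost_matching(
    det_xy: np.ndarray, tru_xy: np.ndarray, max_dist: float
) -> list[tuple[int, int]]:
    """Minimum-total-distance one-to-one assignment by enumerating subsets.

    Only usable for tiny instances; pairs farther than ``max_dist`` are
    forbidden.
    """
    from itertools import permutations

    det_xy = np.asarray(det_xy, dtype=float)
    tru_xy = np.asarray(tru_xy, dtype=float)
    n_d, n_t = len(det_xy), len(tru_xy)
    dist = np.linalg.norm(det_xy[:, None, :] - tru_xy[None, :, :], axis=2)
    best_pairs: list[tuple[int, int]] = []
    best_key = (0, 0.0)  # (-n matched, total distance); maximize matches, then min cost
    for k in range(min(n_d, n_t), 0, -1):
        found = None
        from itertools import combinations

        for det_subset in combinations(range(n_d), k):
            for tru_perm in permutations(range(n_t), k):
                if all(dist[d, t] <= max_dist for d, t in zip(det_subset, tru_perm)):
                    cost = sum(dist[d, t] for d, t in zip(det_subset, tru_perm))
                    if found is None or cost < found[0]:
                        found = (cost, list(zip(det_subset, tru_perm)))
        if found is not None:
            best_pairs = found[1]
            break
    return best_pairs


def normal_equations_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R^2 by the closed-form normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return float(slope), float(intercept), 1.0 - ss_res / ss_tot
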