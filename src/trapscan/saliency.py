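"""Spectral-residual saliency for one sub-block.

An image decomposes into a statistically redundant part (the smooth card
background) and a novelty part (the insects).  In the frequency domain the
redundant part dominates the smooth trend of the log-amplitude spectrum, so
subtracting a local average of the log spectrum leaves a *spectral
residual* carrying mostly the novelty.  Transforming the residual back with
the original phase and squaring yields a per-pixel saliency score; a small
Gaussian blur suppresses single-pixel artifacts.

The steps, for a single-channel block I(x):

    A(f) = |F[I]|                       amplitude spectrum
    P(f) = arg F[I]                     phase spectrum
    L(f) = log(A(f) + eps)              log spectrum
    R(f) = L(f) - h_n * L(f)            residual (h_n = n x n mean filter)
    S(x) = g * |F^-1[exp(R + iP)]|^2    saliency (g = Gaussian)

The map is finally min-max normalized to [0, 1]; a near-constant map (no
novelty) is returned as all zeros rather than amplifying numerical noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as _fft
from scipy import ndimage

from .colorspaces import rgb_to_luma_u8

MIN_BLOCK_SIDE = 8

#: below this pre-normalization dynamic range a map is treated as flat
FLAT_MAP_SPAN = 1e-12


@dataclass(frozen=True)
class SaliencyParams:
    """Tunables of the spectral-residual transform.

    avg_filter_size:
        Support of the uniform filter h_n that estimates the smooth trend of
        the log spectrum; odd, >= 3.
    gauss_sigma:
        Width (px) of the final Gaussian g.  Kept below the target radius:
        a wider blur inflates each object's half-maximum support past the
        plausible-size band and neighbouring insects merge into one peak.
    log_epsilon:
        Guard added to the amplitude before the logarithm (zero bins occur
        for exactly symmetric inputs).
    """

    avg_filter_size: int = 3
    gauss_sigma: float = 0.8
    log_epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if self.avg_filter_size < 3 or self.avg_filter_size % 2 == 0:
            raise ValueError("avg_filter_size must be odd and >= 3")
        if self.gauss_sigma <= 0:
            raise ValueError("gauss_sigma must be positive")
        if self.log_epsilon <= 0:
            raise ValueError("log_epsilon must be positive")


@dataclass
class SaliencyMap:
    """Normalized per-pixel novelty scores for one block."""

    values: np.ndarray
    block_offset: tuple[int, int] = (0, 0)
    params: SaliencyParams = field(default_factory=SaliencyParams)
    raw_span: float = 0.0  # pre-normalization max-min, for diagnostics


def spectral_residual_raw(
    block_gray: np.ndarray, params: SaliencyParams | None = None
) -> np.ndarray:
    """The transform without the final normalization (float64 map)."""
    params = params or SaliencyParams()
    gray = np.asarray(block_gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("expected a 2-D single-channel block")
    if min(gray.shape) < MIN_BLOCK_SIDE:
        raise ValueError(f"block sides must be >= {MIN_BLOCK_SIDE}px")
    if not np.all(np.isfinite(gray)):
        raise ValueError("block contains non-finite values")
    if gray.max() == gray.min():
        # no structure at all: the transform's off-DC bins are pure FFT
        # rounding noise that exp() would amplify into spurious texture
        return np.zeros_like(gray)

    spectrum = _fft.fft2(gray)
    amplitude = np.abs(spectrum)
    phase = np.angle(spectrum)
    log_amp = np.log(amplitude + params.log_epsilon)
    trend = ndimage.uniform_filter(log_amp, size=params.avg_filter_size, mode="nearest")
    residual = log_amp - trend
    recon = _fft.ifft2(np.exp(residual + 1j * phase))
    return ndimage.gaussian_filter(np.abs(recon) ** 2, sigma=params.gauss_sigma)


def spectral_residual(
    block_gray: np.ndarray,
    params: SaliencyParams | None = None,
    block_offset: tuple[int, int] = (0, 0),
) -> SaliencyMap:
    """Compute the normalized spectral-residual saliency map of a block."""
    params = params or SaliencyParams()
    raw = spectral_residual_raw(block_gray, params)
    lo, hi = float(raw.min()), float(raw.max())
    span = hi - lo
    if span < FLAT_MAP_SPAN:
        values = np.zeros_like(raw)
    else:
        values = (raw - lo) / span
    return SaliencyMap(values=values, block_offset=block_offset, params=params, raw_span=span)


def block_to_gray(block) -> np.ndarray:
    """BT.601 luma plane of a sub-block (accepts a SubBlock or an RGB array)."""
    pixels = getattr(block, "pixels", block)
    return rgb_to_luma_u8(pixels)
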