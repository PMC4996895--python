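"""Multi-scale texture layers for predictor bands.

Two neighborhood summaries are computed per band and window scale:

* a Gaussian-weighted local mean, with weights
  ``W_g(x, y) = exp(-(x^2 + y^2) / (2 sigma^2))`` normalized to sum to 1
  over the window, and
* the local standard deviation, using the population (1/N) denominator.

Defaults follow the mapping study design: windows 5x5, 9x9, 17x17 and
33x33 with sigma 1, 2, 4 and 8 respectively, applied to every optical,
radar and elevation band at the working resolution.

Edge and mask handling: neighbors that fall outside the grid or are
masked are excluded and the weights renormalized over what remains, so
no data is invented at scene edges.  An output cell whose whole window
is masked is masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError
from .raster_io import LayerStack, Raster

DEFAULT_WINDOWS = (5, 9, 17, 33)
DEFAULT_SIGMAS = (1.0, 2.0, 4.0, 8.0)


@dataclass(frozen=True)
class TextureSpec:
    """Window/scale plan for texture generation."""

    window_sizes: tuple[int, ...] = DEFAULT_WINDOWS
    sigmas: tuple[float, ...] = DEFAULT_SIGMAS
    include_local_sd: bool = True

    def __post_init__(self) -> None:
        if len(self.window_sizes) != len(self.sigmas):
            raise InvalidParameterError(
                "window_sizes and sigmas must have equal length")
        for w in self.window_sizes:
            if w % 2 == 0 or w < 3:
                raise InvalidParameterError(
                    f"window sizes must be odd and >= 3, got {w}")
        for s in self.sigmas:
            if s <= 0:
                raise InvalidParameterError(f"sigma must be > 0, got {s}")

    @property
    def layers_per_band(self) -> int:
        n = len(self.window_sizes)
        return n * 2 if self.include_local_sd else n


def _check_window(window: int) -> int:
    if window % 2 == 0 or window < 3:
        raise InvalidParameterError(
            f"window must be odd and >= 3, got {window}")
    return window // 2


def _masked_window_sums(band: Raster, kernel: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Window sums of kernel*z and of the kernel over valid cells only."""
    valid = band.valid_mask.astype(float)
    z = np.where(band.valid_mask, band.values, 0.0)
    num = ndimage.convolve(z, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
    return num, den


def gaussian_texture(band: Raster, window: int, sigma: float) -> Raster:
    """Gaussian-weighted local mean over an odd square window."""
    half = _check_window(window)
    if sigma <= 0:
        raise InvalidParameterError(f"sigma must be > 0, got {sigma}")
    off = np.arange(-half, half + 1)
    xx, yy = np.meshgrid(off, off, indexing="ij")
    kernel = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    num, den = _masked_window_sums(band, kernel)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    return Raster(out, band.transform, nodata_mask=(den <= 0))


def local_sd_texture(band: Raster, window: int) -> Raster:
    """Population standard deviation over an odd square window.

    Computed from window moments of the mean-centered band (centering
    stabilizes the E[z^2] - E[z]^2 cancellation for bands with a large
    offset, and leaves the SD unchanged).
    """
    _check_window(window)
    kernel = np.ones((window, window))
    centered = band.copy()
    vv = band.valid_values()
    if vv.size:
        centered.values = band.values - vv.mean()
    s1, counts = _masked_window_sums(centered, kernel)
    sq = Raster(centered.values**2, band.transform, band.nodata_mask.copy())
    s2, _ = _masked_window_sums(sq, kernel)
    with np.errstate(invalid="ignore", divide="ignore"):
        n = np.maximum(counts, 1e-300)
        var = s2 / n - (s1 / n) ** 2
        out = np.where(counts > 0, np.sqrt(np.clip(var, 0.0, None)), np.nan)
    return Raster(out, band.transform, nodata_mask=(counts <= 0))


def build_texture_stack(stack: LayerStack,
                        spec: TextureSpec = TextureSpec()) -> LayerStack:
    """Append texture layers (role 'T') for every non-texture band.

    For each input band, one Gaussian layer per (window, sigma) pair and,
    when ``include_local_sd``, one local-SD layer per window.  Layer names
    encode band, filter and scale (e.g. ``L1_gauss_w9_s2``, ``A_HV_sd_w33``).
    """
    out = LayerStack(list(stack.bands), list(stack.roles), list(stack.names))
    for band, role, name in zip(stack.bands, stack.roles, stack.names):
        if role == "T":
            continue
        for w, s in zip(spec.window_sizes, spec.sigmas):
            out.append(gaussian_texture(band, w, s), "T",
                       f"{name}_gauss_w{w}_s{s:g}")
        if spec.include_local_sd:
            for w in spec.window_sizes:
                out.append(local_sd_texture(band, w), "T", f"{name}_sd_w{w}")
    return out
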