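"""Median-filter preprocessing for CT slices.

Brain-CT slices carry impulse (salt-and-pepper) and sensor noise that
disturbs histogram-based segmentation downstream.  A median filter removes
impulse noise without blurring lesion boundaries the way a linear filter
would, and never introduces intensity values absent from the input.

Two implementations of the same filter are provided:

``median_filter_naive``
    sorts each window and picks the lower median — the reference.

``median_filter_bisection``
    locates the median by bisecting the intensity range and counting how
    many window pixels fall in each half, never materialising a full
    histogram.  It is exactly equivalent to the naive filter on every
    input; it exists because the bisection strategy is the one the method
    is defined with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from PIL import Image

__all__ = [
    "MedianFilterConfig",
    "median_filter_naive",
    "median_filter_bisection",
    "add_gaussian_noise",
    "add_salt_pepper_noise",
    "psnr",
    "load_grayscale",
    "save_grayscale",
    "load_nifti_slices",
]

_BORDER_MODES = {"reflect": "symmetric", "edge": "edge", "constant-zero": "constant"}


@dataclass(frozen=True)
class MedianFilterConfig:
    """Window side length (odd) and border handling for the median filter."""

    window: int = 3
    border_mode: str = "reflect"

    def validate(self, shape: tuple[int, int]) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")
        if self.border_mode not in _BORDER_MODES:
            raise ValueError(
                f"border_mode must be one of {sorted(_BORDER_MODES)}, got {self.border_mode!r}"
            )
        if self.window > min(shape):
            raise ValueError(
                f"window {self.window} exceeds image extent {min(shape)}"
            )


def _validate_image(image: np.ndarray, levels: int) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"expected integer intensities, got dtype {arr.dtype}")
    if arr.min() < 0 or arr.max() > levels - 1:
        raise ValueError(f"intensities must lie in [0, {levels - 1}]")
    return arr


def _padded_windows(
    image: np.ndarray, cfg: MedianFilterConfig
) -> np.ndarray:
    pad = cfg.window // 2
    mode = _BORDER_MODES[cfg.border_mode]
    kwargs = {"constant_values": 0} if mode == "constant" else {}
    padded = np.pad(image, pad, mode=mode, **kwargs)
    return sliding_window_view(padded, (cfg.window, cfg.window))


def median_filter_naive(
    image: np.ndarray,
    cfg: MedianFilterConfig | None = None,
    levels: int = 256,
) -> np.ndarray:
    """Median filter by sorting each window (lower median for even counts)."""
    cfg = cfg or MedianFilterConfig()
    arr = _validate_image(image, levels)
    cfg.validate(arr.shape)
    win = _padded_windows(arr, cfg)
    flat = win.reshape(*arr.shape, -1)
    n = flat.shape[-1]
    # lower median: (n-1)//2-th order statistic, exact for integer data
    part = np.partition(flat, (n - 1) // 2, axis=-1)
    return part[..., (n - 1) // 2].astype(arr.dtype)


def median_filter_bisection(
    image: np.ndarray,
    cfg: MedianFilterConfig | None = None,
    levels: int = 256,
) -> np.ndarray:
    """Median filter by bisection search on the intensity range.

    Per window the candidate range [lo, hi] is halved each round; the half
    that (together with pixels already discarded below ``lo``) holds at
    least half the window count is kept, ties going to the lower half,
    until the range converges to a single intensity.  Equals
    :func:`median_filter_naive` exactly on every input.
    """
    cfg = cfg or MedianFilterConfig()
    arr = _validate_image(image, levels)
    cfg.validate(arr.shape)
    win = _padded_windows(arr, cfg).reshape(*arr.shape, -1)
    n = win.shape[-1]
    rank = (n - 1) // 2 + 1  # 1-based rank of the lower median

    lo = np.zeros(arr.shape, dtype=np.int64)
    hi = np.full(arr.shape, levels - 1, dtype=np.int64)
    below = np.zeros(arr.shape, dtype=np.int64)  # pixels strictly below lo
    while np.any(lo < hi):
        mid = (lo + hi) // 2
        in_low = (
            (win >= lo[..., None]) & (win <= mid[..., None])
        ).sum(axis=-1)
        take_low = below + in_low >= rank
        hi = np.where(take_low, mid, hi)
        new_lo = np.where(take_low, lo, mid + 1)
        below = np.where(take_low, below, below + in_low)
        lo = new_lo
    return lo.astype(arr.dtype)


# ---------------------------------------------------------------------------
# noise models and fidelity metric used by tests and the synthetic generator

def add_gaussian_noise(
    image: np.ndarray, sigma: float, rng: np.random.Generator, levels: int = 256
) -> np.ndarray:
    """Additive Gaussian noise, rounded and clipped back to [0, levels-1]."""
    noisy = np.asarray(image, dtype=float) + rng.normal(0.0, sigma, image.shape)
    return np.clip(np.rint(noisy), 0, levels - 1).astype(np.uint8 if levels <= 256 else np.int64)


def add_salt_pepper_noise(
    image: np.ndarray, rate: float, rng: np.random.Generator, levels: int = 256
) -> np.ndarray:
    """Impulse noise: exactly round(rate * n_pixels) pixels set to 0 or L-1."""
    if not 0.0 <= rate < 0.5:
        raise ValueError(f"salt-pepper rate must be in [0, 0.5), got {rate}")
    out = np.array(image, copy=True)
    n_corrupt = int(round(rate * out.size))
    if n_corrupt == 0:
        return out
    idx = rng.choice(out.size, size=n_corrupt, replace=False)
    salt = rng.random(n_corrupt) < 0.5
    flat = out.reshape(-1)
    flat[idx[salt]] = levels - 1
    flat[idx[~salt]] = 0
    return out


def psnr(image: np.ndarray, reference: np.ndarray, levels: int = 256) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    diff = np.asarray(image, dtype=float) - np.asarray(reference, dtype=float)
    mse = float(np.mean(diff**2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10((levels - 1) ** 2 / mse)


# ---------------------------------------------------------------------------
# I/O

def load_grayscale(path) -> np.ndarray:
    """Read PNG/JPEG as 8-bit grayscale (colour converted by luminance)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def save_grayscale(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)


def load_nifti_slices(
    path, window_center: float = 40.0, window_width: float = 120.0
) -> list[np.ndarray]:
    """Slice a NIfTI volume along its last axis, windowed linearly to [0, 255].

    The default window (centre 40, width 120) is a generous brain/blood
    window; acute haemorrhage (~50-90 HU) maps to the bright end.
    """
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
    if vol.ndim == 2:
        vol = vol[..., None]
    lo = window_center - window_width / 2.0
    scaled = np.clip((vol - lo) / window_width, 0.0, 1.0) * 255.0
    return [np.rint(scaled[..., k]).astype(np.uint8) for k in range(scaled.shape[-1])]
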