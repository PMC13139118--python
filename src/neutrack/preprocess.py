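"""Image-quality chain for time-lapse frames.

The chain mirrors the acquisition workflow: collapse the z-stack by
maximum intensity projection, then per frame apply contrast enhancement,
median denoising and Gaussian smoothing — in that order.  All filters use
reflective boundary handling so outputs are bit-reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

__all__ = [
    "max_intensity_project",
    "enhance_contrast",
    "denoise_median",
    "smooth_gaussian",
    "preprocess_frame",
    "preprocess_sequence",
]


def max_intensity_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum across the layers of a z-stack.

    ``stack`` is (n_layers, h, w) or a sequence of equally shaped 2-D
    layers; a single layer projects to itself.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be a non-empty sequence of 2-D layers")
    return stack.max(axis=0)


def enhance_contrast(frame: np.ndarray, low_pct: float = 1.0,
                     high_pct: float = 99.8,
                     out_range: tuple[float, float] = (0.0, 255.0)
                     ) -> np.ndarray:
    """Percentile linear stretch: map [P_low, P_high] to ``out_range``.

    Intensities outside the window are clipped; a degenerate frame
    (P_low == P_high) is returned as a constant frame with a warning.
    """
    if not 0.0 <= low_pct < high_pct <= 100.0:
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    frame = np.asarray(frame, dtype=np.float64)
    lo, hi = np.percentile(frame, [low_pct, high_pct])
    out_lo, out_hi = out_range
    if hi <= lo:
        warnings.warn("degenerate frame: contrast window has zero width",
                      stacklevel=2)
        return np.full_like(frame, out_lo)
    stretched = (frame - lo) / (hi - lo) * (out_hi - out_lo) + out_lo
    return np.clip(stretched, out_lo, out_hi)


def denoise_median(frame: np.ndarray, radius: int = 1) -> np.ndarray:
    """Median filter with a (2*radius+1) square window, reflected edges."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return ndimage.median_filter(np.asarray(frame, dtype=np.float64),
                                 size=2 * radius + 1, mode="reflect")


def smooth_gaussian(frame: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Gaussian blur with a normalised kernel (intensity-conserving)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return ndimage.gaussian_filter(np.asarray(frame, dtype=np.float64),
                                   sigma=sigma, mode="reflect")


def preprocess_frame(frame: np.ndarray, low_pct: float = 1.0,
                     high_pct: float = 99.8, median_radius: int = 1,
                     gaussian_sigma: float = 1.0) -> np.ndarray:
    """Default chain: contrast stretch -> median -> Gaussian."""
    out = enhance_contrast(frame, low_pct, high_pct)
    out = denoise_median(out, median_radius)
    return smooth_gaussian(out, gaussian_sigma)


def preprocess_sequence(frames, **kwargs) -> list[np.ndarray]:
    return [preprocess_frame(f, **kwargs) for f in frames]
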