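"""Spatial speckle contrast and precision / image-quality metrics.

The central quantity is the spatial speckle contrast K = sigma(I)/<I>
computed over a sliding pixel neighbourhood.  Measurement precision is
scored by the mean relative per-pixel error

    Error = mean over non-overlapping neighbourhoods and frames of
            |K - K_ref| / K_ref * 100%,

where K_ref is either the contrast averaged over the whole data set
(precision against the ensemble mean) or a noise-free reference map
(camera-noise error).  Overlapping neighbourhoods share pixels and are not
statistically independent, so only a stride-`w` subgrid of windows enters
the error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.ndimage import binary_dilation, uniform_filter

from .errors import DomainError, ParameterError
from .field_synthesis import FrameStack

__all__ = [
    "ContrastMap",
    "ErrorReport",
    "spatial_contrast",
    "contrast_stack",
    "global_contrast",
    "speckle_size_fwhm",
    "per_pixel_error",
    "bfi",
    "sharpness",
    "artefact_mask",
]


@dataclass
class ContrastMap:
    """Per-pixel K values over the valid (fully inside) window positions.

    ``values[i, j]`` is the contrast of the window centred at frame pixel
    ``(i + w//2, j + w//2)``.  ``mask`` is True where K is defined.
    """

    values: np.ndarray
    neighbourhood: int
    exposure_T: float = 0.0
    mask: np.ndarray = None  # True = valid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class ErrorReport:
    """Mean relative per-pixel contrast error (the precision metric)."""

    error_percent: float
    neighbourhood: int
    n_independent_samples: int
    reference: str  # 'dataset_mean' | 'noise_free'
    mean_contrast: float = float("nan")


def _check_window(w: int, shape) -> int:
    w = int(w)
    if w < 2:
        raise ParameterError("neighbourhood must be an integer >= 2")
    if w > min(shape):
        raise ParameterError("neighbourhood larger than the frame")
    return w


def spatial_contrast(
    frame: np.ndarray, neighbourhood: int = 5, ddof: int = 1
) -> ContrastMap:
    """Sliding-window K = sigma(I)/<I> over the valid region of a frame.

    Uses the sample standard deviation (``ddof=1``) by default; windows
    with zero mean are masked rather than raising.
    """
    frame = np.asarray(frame, dtype=np.float64)
    w = _check_window(neighbourhood, frame.shape)
    n = w * w
    m = uniform_filter(frame, w, mode="constant")
    m2 = uniform_filter(frame * frame, w, mode="constant")
    var = m2 - m * m
    if ddof:
        var *= n / (n - ddof)
    # crop to windows fully inside the frame (handles even window sizes,
    # e.g. the 50x50 neighbourhood, where the centre is offset by half a px)
    h, tail = w // 2, w - 1 - w // 2
    sl = (slice(h, frame.shape[0] - tail), slice(h, frame.shape[1] - tail))
    m, var = m[sl], np.maximum(var[sl], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.sqrt(var) / m
    valid = m != 0
    k[~valid] = np.nan
    return ContrastMap(values=k, neighbourhood=w, mask=valid)


def contrast_stack(
    stack: Union[FrameStack, np.ndarray], neighbourhood: int = 5, ddof: int = 1
) -> np.ndarray:
    """3-D array of per-frame contrast maps (time, rows', cols')."""
    frames = stack.frames if isinstance(stack, FrameStack) else np.asarray(stack)
    return np.stack(
        [spatial_contrast(f, neighbourhood, ddof).values for f in frames]
    )


def global_contrast(frames: Union[FrameStack, np.ndarray]) -> float:
    """Whole-frame K = sigma(I)/<I>, averaged over frames."""
    f = frames.frames if isinstance(frames, FrameStack) else np.asarray(frames)
    f = np.atleast_3d(f if f.ndim != 2 else f[None])
    return float(np.mean(f.std(axis=(1, 2), ddof=1) / f.mean(axis=(1, 2))))


# ---------------------------------------------------------------------------
# speckle size
# ---------------------------------------------------------------------------

def _axis_fwhm(profile: np.ndarray) -> float:
    """Full width at half maximum from a one-sided autocovariance profile.

    ``profile[0]`` is the (normalised) zero-lag peak; the crossing of 0.5 is
    located by linear interpolation between lags.
    """
    below = np.where(profile < 0.5)[0]
    if len(below) == 0:
        return float("nan")
    i = below[0]
    if i == 0:
        return float("nan")
    x = (i - 1) + (profile[i - 1] - 0.5) / (profile[i - 1] - profile[i])
    return 2.0 * x


def _fwhm_of_autocov(acov: np.ndarray) -> float:
    cy, cx = acov.shape[0] // 2, acov.shape[1] // 2
    row = _axis_fwhm(acov[cy, cx:])
    col = _axis_fwhm(acov[cy:, cx])
    return float(np.nanmean([row, col]))


def speckle_size_fwhm(frame: Union[np.ndarray, FrameStack]) -> float:
    """Speckle size: FWHM of the spatial autocovariance, in pixels.

    The frame is mean-subtracted, its circular autocovariance computed by
    FFT and peak-normalised; the row- and column-axis FWHM (linear
    interpolation between integer lags) are averaged.  If a `FrameStack` is
    given, the autocovariance is averaged over frames before the FWHM is
    read off, which stabilises the estimate.

    When the autocovariance is non-positive at every nonzero lag (speckle
    at or below the pixel scale) the pixel-scale lower bound 1.0 is returned
    with a warning.
    """
    frames = frame.frames if isinstance(frame, FrameStack) else np.asarray(frame)
    if frames.ndim == 2:
        frames = frames[None]
    acc = np.zeros(frames.shape[1:], dtype=np.float64)
    for f in frames:
        g = f.astype(np.float64) - f.mean()
        F = np.fft.fft2(g)
        acc += np.fft.ifft2(np.abs(F) ** 2).real
    acov = np.fft.fftshift(acc)
    acov /= acov.max()
    out = _fwhm_of_autocov(acov)
    if not np.isfinite(out) or out < 1.0:
        warnings.warn(
            "speckle at or below the pixel scale; returning lower bound 1 px",
            stacklevel=2,
        )
        return 1.0
    return out


# ---------------------------------------------------------------------------
# precision metric
# ---------------------------------------------------------------------------

def _nonoverlapping(values: np.ndarray, w: int) -> np.ndarray:
    """Stride-w subgrid of window centres, anchored at the frame origin."""
    return values[..., ::w, ::w]


def per_pixel_error(
    kmaps: Union[Sequence[ContrastMap], np.ndarray],
    reference: Union[str, ContrastMap] = "dataset_mean",
    neighbourhood: Optional[int] = None,
) -> ErrorReport:
    """Mean relative per-pixel error of K over non-overlapping windows.

    Parameters
    ----------
    kmaps
        Sequence of `ContrastMap` (or a 3-D array of K maps, in which case
        ``neighbourhood`` must be given) from statistically independent
        frames.
    reference
        ``'dataset_mean'`` compares each window against <K> over the whole
        data set; a `ContrastMap` compares against that (noise-free)
        reference per pixel.
    """
    if isinstance(kmaps, np.ndarray):
        if neighbourhood is None:
            raise ParameterError("neighbourhood required with a bare array")
        w = int(neighbourhood)
        values = kmaps
        masks = np.isfinite(values)
    else:
        kmaps = list(kmaps)
        w = kmaps[0].neighbourhood
        if any(km.neighbourhood != w for km in kmaps):
            raise ParameterError("all maps must share a neighbourhood size")
        values = np.stack([km.values for km in kmaps])
        masks = np.stack([km.mask for km in kmaps])

    sub = _nonoverlapping(values, w)
    sub_mask = _nonoverlapping(masks, w)

    if isinstance(reference, ContrastMap):
        ref = _nonoverlapping(reference.values, w)
        ref_mask = _nonoverlapping(reference.mask, w)
        if np.any(ref[ref_mask] == 0):
            raise DomainError("reference contrast contains zeros")
        ok = sub_mask & ref_mask[None] & (ref[None] != 0)
        err = np.abs(sub[ok] - np.broadcast_to(ref, sub.shape)[ok]) / np.broadcast_to(
            ref, sub.shape
        )[ok]
        ref_kind = "noise_free"
        kmean = float(np.nanmean(sub[ok]))
    else:
        if reference != "dataset_mean":
            raise ParameterError("reference must be 'dataset_mean' or a ContrastMap")
        if sub.shape[0] < 2:
            raise ParameterError(
                "dataset_mean reference needs >= 2 independent maps"
            )
        kmean = float(sub[sub_mask].mean())
        if kmean == 0:
            raise DomainError("dataset mean contrast is zero")
        err = np.abs(sub[sub_mask] - kmean) / kmean
        ref_kind = "dataset_mean"

    return ErrorReport(
        error_percent=float(err.mean() * 100.0),
        neighbourhood=w,
        n_independent_samples=int(err.size),
        reference=ref_kind,
        mean_contrast=kmean,
    )


def bfi(kmap: ContrastMap) -> ContrastMap:
    """Blood flow index BFI = 1/K^2 (qualitative perfusion proxy).

    Pixels with K = 0 are masked; the input mask is propagated.
    """
    k = kmap.values
    mask = kmap.mask & (k != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 1.0 / (k * k)
    out[~mask] = np.nan
    return ContrastMap(
        values=out, neighbourhood=kmap.neighbourhood,
        exposure_T=kmap.exposure_T, mask=mask,
    )


def sharpness(kmap: ContrastMap) -> float:
    """Image sharpness: mean 3x3 spatial contrast of the contrast image.

    A 'contrast of contrast' — flat K maps score 0, step edges score high.
    Scale-invariant: sharpness(c*K) = sharpness(K) for c > 0.  Windows
    containing masked pixels are excluded.
    """
    vals = np.where(kmap.mask, kmap.values, 0.0)
    if min(vals.shape) < 3:
        raise ParameterError("unmasked area smaller than 3x3")
    cmap = spatial_contrast(vals, 3)
    # exclude 3x3 windows touching any masked pixel
    ok_input = uniform_filter(kmap.mask.astype(np.float64), 3, mode="constant")
    ok = ok_input[1:-1, 1:-1] > 1.0 - 1e-9
    sel = cmap.mask & ok
    if not sel.any():
        raise ParameterError("no fully unmasked 3x3 window")
    return float(cmap.values[sel].mean())


def artefact_mask(
    intensity_stacks: Union[FrameStack, Sequence[FrameStack]],
    kmap_stacks: Optional[Sequence[np.ndarray]] = None,
    i_bounds: Optional[tuple] = None,
    k_bounds: tuple = (1e-4, 0.99),
    dn_max: Optional[float] = None,
    dilation_radius: int = 2,
):
    """Flag artefact pixels (e.g. specular saturation) plus a 2-px halo.

    A pixel is an artefact if in ANY time point of ANY recording its
    intensity leaves the open interval ``(0, DN_max)`` or its contrast
    leaves ``k_bounds``.  The mask is dilated by a Chebyshev radius
    (square structuring element), default 2 px.

    Returns ``(mask, fraction)`` where mask is True at artefact pixels.
    """
    if isinstance(intensity_stacks, FrameStack):
        intensity_stacks = [intensity_stacks]
    shape = intensity_stacks[0].shape
    bad = np.zeros(shape, dtype=bool)
    for st in intensity_stacks:
        if st.units != "DN":
            raise ParameterError("artefact bounds are defined on DN stacks")
        if i_bounds is None:
            hi = dn_max if dn_max is not None else float(np.max(st.frames))
            lo = 0.0
        else:
            lo, hi = i_bounds
        viol = (st.frames <= lo) | (st.frames >= hi)
        bad |= viol.any(axis=0)
    if kmap_stacks is not None:
        klo, khi = k_bounds
        for ks in kmap_stacks:
            ks = np.asarray(ks)
            if ks.ndim == 2:
                ks = ks[None]
            w_off = (shape[0] - ks.shape[1]) // 2
            kbad = ((ks <= klo) | (ks >= khi) | ~np.isfinite(ks)).any(axis=0)
            sub = np.zeros(shape, dtype=bool)
            sub[w_off: w_off + ks.shape[1], w_off: w_off + ks.shape[2]] = kbad
            bad |= sub
    if dilation_radius > 0 and bad.any():
        size = 2 * dilation_radius + 1
        bad = binary_dilation(bad, structure=np.ones((size, size), dtype=bool))
    return bad, float(bad.mean())
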