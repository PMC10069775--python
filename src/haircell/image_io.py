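"""Micrograph loading and normalization.

Images enter the pipeline as :class:`MultiChannelImage`: a ``(channel, row,
col)`` float array normalized to [0, 1], a physical pixel size in nm/px, and
optional per-channel role tags (``cell_body`` for a cytoplasmic hair-cell
marker such as anti-MYO7A, ``bundle`` for a stereocilia stain such as
phalloidin). Multi-page stacks are collapsed to a 2D maximum intensity
projection before any analysis; channel order is preserved as stored and has
no effect on downstream results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from skimage.transform import rescale as _sk_rescale

from .errors import InputError, UnsupportedFormatError

MAX_CHANNELS = 4

#: Channel roles understood by the pipeline.
CHANNEL_ROLES = ("cell_body", "bundle", "other")


@dataclass
class MultiChannelImage:
    """A 2D fluorescence micrograph with 1-4 channels.

    Attributes
    ----------
    pixels : ndarray, shape (C, H, W)
        Non-negative intensities, normalized to [0, 1].
    pixel_size_nm : float
        Physical size of one pixel in nanometres; must be positive.
    channel_roles : dict[int, str]
        Optional map channel index -> role (``cell_body``/``bundle``/``other``).
    """

    pixels: np.ndarray
    pixel_size_nm: float
    channel_roles: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise InputError(
                f"pixels must be (channel, row, col); got shape {self.pixels.shape}"
            )
        n_ch = self.pixels.shape[0]
        if not (1 <= n_ch <= MAX_CHANNELS):
            raise UnsupportedFormatError(
                f"images must have 1-{MAX_CHANNELS} channels; got {n_ch}"
            )
        if not np.all(np.isfinite(self.pixels)) or self.pixels.min() < 0:
            raise InputError("pixel intensities must be finite and non-negative")
        if not (np.isscalar(self.pixel_size_nm) or np.ndim(self.pixel_size_nm) == 0):
            raise InputError("pixel_size_nm must be a scalar")
        if self.pixel_size_nm <= 0:
            raise InputError(f"pixel_size_nm must be positive; got {self.pixel_size_nm}")
        for idx, role in self.channel_roles.items():
            if not (0 <= idx < n_ch):
                raise InputError(f"channel role index {idx} out of range")
            if role not in CHANNEL_ROLES:
                raise InputError(f"unknown channel role {role!r}")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple:
        """(rows, cols) spatial shape."""
        return self.pixels.shape[1:]

    def channel_with_role(self, role: str, default: int | None = None) -> int:
        """Index of the first channel tagged with *role*, else *default*."""
        for idx in sorted(self.channel_roles):
            if self.channel_roles[idx] == role:
                return idx
        if default is None:
            raise InputError(f"no channel tagged {role!r} and no default given")
        return default

    @property
    def um_per_px(self) -> float:
        return self.pixel_size_nm / 1000.0


def _normalize_dtype(arr: np.ndarray) -> np.ndarray:
    """Scale integer bit depths (and out-of-range floats) into [0, 1]."""
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / float(max(info.max, 1))
    arr = arr.astype(np.float64)
    m = arr.max(initial=0.0)
    if m > 1.0:
        arr = arr / m
    return np.clip(arr, 0.0, None)


def _interpret_tiff_axes(shape: tuple, axes: str | None) -> tuple:
    """Identify (z_axis, channel_axis) for a TIFF array.

    The series' axes string is used when it names channel (C/S) or page
    (Z/T/I/Q) axes. Otherwise, fall back to a shape heuristic: the smallest
    leading axis of length <= 4 is the channel axis; the last two axes are
    always spatial; any remaining leading axis is the page (z) axis.
    """
    ndim = len(shape)
    lead = list(range(ndim - 2))
    if axes is not None and len(axes) == ndim:
        ch = [i for i in lead if axes[i] in "CS"]
        zs = [i for i in lead if axes[i] in "ZTIQ"]
        # trailing sample axis (YXS): move handled by caller via moveaxis
        if axes.endswith("S"):
            ch = [ndim - 1]
            lead = [i for i in range(ndim) if i != ndim - 1 and axes[i] not in "YX"]
            zs = [i for i in lead if axes[i] in "ZTIQ"]
        if len(ch) <= 1 and len(zs) <= 1 and (ch or zs):
            return (zs[0] if zs else None), (ch[0] if ch else None)
    ch_candidates = [ax for ax in lead if shape[ax] <= MAX_CHANNELS]
    ch_axis = min(ch_candidates, key=lambda ax: shape[ax]) if ch_candidates else None
    z_axes = [ax for ax in lead if ax != ch_axis]
    if len(z_axes) > 1:
        raise UnsupportedFormatError(f"cannot interpret image of shape {shape}")
    z_axis = z_axes[0] if z_axes else None
    if ch_axis is None and z_axis is None:
        raise UnsupportedFormatError(f"cannot interpret image of shape {shape}")
    return z_axis, ch_axis


def load_image(path, pixel_size_nm: float = 288.0, channel_roles: dict | None = None) -> MultiChannelImage:
    """Read a TIFF/PNG/JPEG micrograph.

    Multi-page TIFFs are max-projected along the page axis. Grayscale files
    yield one channel; RGB(A) planes are treated as channels. Channel order
    is never altered.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    axes = None
    try:
        if suffix in (".tif", ".tiff"):
            with tifffile.TiffFile(str(path)) as tf:
                series = tf.series[0]
                arr = series.asarray()
                axes = series.axes  # e.g. 'YX', 'ZYX', 'CYX', 'ZCYX', 'YXS'
        elif suffix in (".png", ".jpg", ".jpeg"):
            with Image.open(path) as im:
                arr = np.asarray(im)
            if arr.ndim == 3:  # (H, W, C) -> (C, H, W)
                arr = np.moveaxis(arr, -1, 0)
        else:
            raise UnsupportedFormatError(f"unsupported image format: {path.name}")
    except (UnsupportedFormatError, InputError):
        raise
    except Exception as exc:  # unreadable/corrupt file
        raise InputError(f"could not read image {path}: {exc}") from exc

    arr = np.asarray(arr)
    if suffix in (".tif", ".tiff"):
        if arr.ndim == 2:
            arr = arr[None]
        else:
            z_axis, ch_axis = _interpret_tiff_axes(arr.shape, axes)
            if z_axis is not None:
                arr = arr.max(axis=z_axis)
                if ch_axis is not None and ch_axis > z_axis:
                    ch_axis -= 1
            if ch_axis is None:
                arr = arr[None]
            elif ch_axis != 0:
                arr = np.moveaxis(arr, ch_axis, 0)
    elif arr.ndim == 2:
        arr = arr[None]

    if arr.shape[0] > MAX_CHANNELS:
        raise UnsupportedFormatError(
            f"{path.name}: {arr.shape[0]} channels exceeds the supported maximum of {MAX_CHANNELS}"
        )
    return MultiChannelImage(
        pixels=_normalize_dtype(arr),
        pixel_size_nm=pixel_size_nm,
        channel_roles=dict(channel_roles or {}),
    )


def max_project(stack: np.ndarray, pixel_size_nm: float = 288.0, channel_roles: dict | None = None) -> MultiChannelImage:
    """Maximum intensity projection of a ``(z, channel, row, col)`` stack.

    A ``(z, row, col)`` single-channel stack is also accepted. A z axis of
    length 1 returns that slice unchanged.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim == 3:
        stack = stack[:, None]
    if stack.ndim != 4:
        raise InputError(f"stack must be (z, channel, row, col); got shape {stack.shape}")
    if stack.shape[0] == 0:
        raise InputError("stack has an empty z axis")
    return MultiChannelImage(
        pixels=stack.max(axis=0),
        pixel_size_nm=pixel_size_nm,
        channel_roles=dict(channel_roles or {}),
    )


def rescale_to_working_resolution(img: MultiChannelImage, target_nm_per_px: float) -> MultiChannelImage:
    """Resample *img* so one pixel spans *target_nm_per_px* nanometres.

    Bilinear interpolation; a no-op when the scale factor is within 1% of 1.
    """
    if target_nm_per_px <= 0:
        raise InputError(f"target_nm_per_px must be positive; got {target_nm_per_px}")
    factor = img.pixel_size_nm / target_nm_per_px
    if abs(factor - 1.0) <= 0.01:
        return img
    out = _sk_rescale(
        img.pixels,
        scale=(1.0, factor, factor),
        order=1,
        anti_aliasing=factor < 1.0,
        preserve_range=True,
    )
    return replace(img, pixels=np.clip(out, 0.0, 1.0), pixel_size_nm=target_nm_per_px)


def adjust_intensity(img: MultiChannelImage, low_percentile: float = 1.0, high_percentile: float = 99.0) -> MultiChannelImage:
    """Per-channel percentile stretch: low/high percentiles map to 0/1, clipped.

    A constant channel cannot be stretched and comes back all-zero with a
    warning.
    """
    if not (0 <= low_percentile < high_percentile <= 100):
        raise InputError(
            f"percentiles must satisfy 0 <= low < high <= 100; got ({low_percentile}, {high_percentile})"
        )
    out = np.empty_like(img.pixels)
    for c in range(img.n_channels):
        ch = img.pixels[c]
        lo, hi = np.percentile(ch, [low_percentile, high_percentile])
        if hi <= lo:
            warnings.warn(f"channel {c} is constant; returning zeros", stacklevel=2)
            out[c] = 0.0
        else:
            out[c] = np.clip((ch - lo) / (hi - lo), 0.0, 1.0)
    return replace(img, pixels=out)
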