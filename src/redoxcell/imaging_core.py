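"""Image data model and shared low-level operations.

The container types here are deliberately thin wrappers around numpy
arrays: an :class:`IntensityImage` is a 2-D nonnegative fluorescence
grid with a channel tag, a :class:`DecayStack` is a (T, H, W) stack of
photon counts from time-correlated single-photon counting, and a
:class:`LabelImage` is an integer object mask (0 = background).

Operations cover what every downstream stage needs: TIFF round-trip,
per-pixel decay integration with spatial binning, circular-average
smoothing, and linear contrast rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "CHANNELS",
    "IntensityImage",
    "DecayStack",
    "LabelImage",
    "read_image",
    "write_image",
    "read_label_image",
    "write_label_image",
    "read_decay_stack",
    "write_decay_stack",
    "integrate_decay",
    "smooth_circular_average",
    "rescale_contrast",
]

#: Recognized fluorescence channels. NADPH/FAD are the autofluorescence
#: cofactor channels; TMRE reports mitochondrial polarization; DAPI,
#: KI67 and CC3 are the immunofluorescence nucleus/proliferation/apoptosis
#: markers.
CHANNELS = ("NADPH", "FAD", "TMRE", "DAPI", "KI67", "CC3")


def _check_channel(channel: str | None) -> str | None:
    if channel is not None and channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    return channel


@dataclass
class IntensityImage:
    """2-D nonnegative fluorescence intensity grid with a channel tag."""

    pixels: np.ndarray
    channel: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"intensity image must be 2-D, got {self.pixels.ndim}-D")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("intensity image must have height, width >= 1")
        if np.any(self.pixels < 0) or not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensity values must be finite and >= 0")
        _check_channel(self.channel)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class DecayStack:
    """(T, H, W) stack of nonnegative integer photon counts per time bin."""

    counts: np.ndarray
    channel: str | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise ValueError(f"decay stack must be 3-D (T, H, W), got {counts.ndim}-D")
        if counts.shape[0] < 1:
            raise ValueError("decay stack needs at least one time bin")
        if np.any(counts < 0):
            raise ValueError("photon counts must be >= 0")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValueError("photon counts must be integers")
            counts = rounded.astype(np.int64)
        self.counts = counts
        _check_channel(self.channel)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[1:]


@dataclass
class LabelImage:
    """Integer object mask; 0 is background, k >= 1 is object k."""

    labels: np.ndarray = field(default_factory=lambda: np.zeros((1, 1), dtype=np.int32))

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError(f"label image must be 2-D, got {labels.ndim}-D")
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if not np.allclose(labels, rounded):
                raise ValueError("labels must be integers")
            labels = rounded
        if labels.min(initial=0) < 0:
            raise ValueError("labels must be >= 0")
        self.labels = labels.astype(np.int32)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def ids(self) -> np.ndarray:
        """Sorted nonzero object ids present in the mask."""
        u = np.unique(self.labels)
        return u[u > 0]


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def read_image(path: str | Path, channel: str | None = None, page: int = 0) -> IntensityImage:
    """Read one plane of a (possibly multi-page) TIFF as an IntensityImage."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        if page >= len(tif.pages):
            raise IndexError(f"page {page} out of range for {path} ({len(tif.pages)} pages)")
        plane = tif.pages[page].asarray()
    if plane.ndim != 2:
        raise ValueError(f"expected a 2-D plane in {path}, got shape {plane.shape}")
    return IntensityImage(plane, channel=channel)


def write_image(img: IntensityImage, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, img.pixels.astype(np.float32))
    return path


def read_label_image(path: str | Path) -> LabelImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"label image must be 2-D, got shape {arr.shape}")
    return LabelImage(arr)


def write_label_image(labels: LabelImage, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, labels.labels.astype(np.int32))
    return path


def read_decay_stack(path: str | Path, channel: str | None = None) -> DecayStack:
    """Read a multi-page TIFF as a photon-count decay stack (pages = time bins)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"decay stack file not found: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return DecayStack(arr, channel=channel)


def write_decay_stack(stack: DecayStack, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.counts.astype(np.uint16))
    return path


# ---------------------------------------------------------------------------
# Pixel operations
# ---------------------------------------------------------------------------

def integrate_decay(stack: DecayStack, bin_radius: int = 1) -> IntensityImage:
    """Collapse a photon-count decay stack to an intensity image.

    The per-pixel intensity is the total photon count over all time bins
    inside a sliding (2r+1) x (2r+1) spatial window centered on the pixel
    (r = ``bin_radius``; r=1 gives the conventional 3x3 bin). Windows are
    truncated at image edges — no padding values are invented — so edge
    pixels integrate over fewer neighbors.
    """
    if bin_radius < 0:
        raise ValueError(f"bin_radius must be >= 0, got {bin_radius}")
    total = stack.counts.sum(axis=0).astype(np.float64)
    if bin_radius == 0:
        out = total
    else:
        size = 2 * bin_radius + 1
        kernel = np.ones((size, size))
        out = ndimage.correlate(total, kernel, mode="constant", cval=0.0)
    return IntensityImage(out, channel=stack.channel)


def _disk_kernel(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2 <= radius**2).astype(np.float64)


def smooth_circular_average(img: IntensityImage, radius: float = 1.0) -> IntensityImage:
    """Circular (disk) average filter with edge renormalization.

    Each pixel becomes the mean of pixels whose center lies within
    Euclidean distance <= radius. Near edges the kernel is renormalized
    over in-bounds pixels only, so constants are preserved everywhere.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    kernel = _disk_kernel(radius)
    num = ndimage.correlate(img.pixels, kernel, mode="constant", cval=0.0)
    den = ndimage.correlate(np.ones_like(img.pixels), kernel, mode="constant", cval=0.0)
    return IntensityImage(num / den, channel=img.channel)


def rescale_contrast(img: IntensityImage, new_max: float) -> IntensityImage:
    """Linearly map [0, max(img)] onto [0, new_max]."""
    if new_max <= 0:
        raise ValueError(f"new_max must be > 0, got {new_max}")
    old_max = float(img.pixels.max())
    if old_max == 0:
        raise ValueError("cannot rescale an all-zero image")
    return IntensityImage(img.pixels * (new_max / old_max), channel=img.channel)
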