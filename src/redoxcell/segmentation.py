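"""Thresholding and nucleus-seeded cell segmentation.

Cells are segmented the way secondary-object identification works in
microscopy pipelines: nuclei (supplied as a label mask) act as seeds,
and each foreground pixel is assigned to the nucleus reachable at
minimal geodesic cost through the guide image. Global thresholds come
from either Otsu's between-class-variance criterion or Li's minimum
cross-entropy criterion, the latter with a multiplicative correction
factor. Derived masks — cytoplasm (cell minus nucleus) and
mitochondria (cytoplasm gated by a global TMRE threshold) — keep the
per-cell label ids so all compartments of a cell share one id.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu as _skimage_otsu
from scipy import ndimage

from .imaging_core import IntensityImage, LabelImage

__all__ = [
    "ThresholdSpec",
    "SegmentationResult",
    "threshold_otsu",
    "threshold_min_cross_entropy",
    "propagate_cells",
    "derive_cytoplasm",
    "mask_mitochondria",
    "measure_compartments",
    "segment_cells",
]


@dataclass
class ThresholdSpec:
    """How to compute a global threshold.

    method           one of {"otsu", "min_cross_entropy", "manual"}
    correction_factor  positive multiplier applied to the computed value
    manual_value     the threshold itself, required iff method == "manual"
    """

    method: str = "min_cross_entropy"
    correction_factor: float = 1.0
    manual_value: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "min_cross_entropy", "manual"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.correction_factor <= 0:
            raise ValueError("correction_factor must be > 0")
        if (self.manual_value is None) == (self.method == "manual"):
            raise ValueError("manual_value required iff method is 'manual'")

    def resolve(self, img: IntensityImage) -> float:
        """Compute the corrected global threshold for an image."""
        if self.method == "manual":
            return float(self.manual_value) * self.correction_factor
        if self.method == "otsu":
            return threshold_otsu(img) * self.correction_factor
        return threshold_min_cross_entropy(img, self.correction_factor)


@dataclass
class SegmentationResult:
    """Per-cell compartment masks sharing one label id per cell."""

    nuclei: LabelImage
    cells: LabelImage
    cytoplasm: LabelImage
    mitochondria: LabelImage

    def validate(self) -> None:
        """Assert the compartment containment relations.

        nucleus(k) ⊆ cell(k); cytoplasm(k) = cell(k) \\ nucleus(k);
        mitochondria(k) ⊆ cytoplasm(k); each cell contains exactly one
        nucleus id (its own).
        """
        nuc, cel = self.nuclei.labels, self.cells.labels
        cyt, mit = self.cytoplasm.labels, self.mitochondria.labels
        nz = nuc > 0
        if not np.array_equal(nuc[nz], cel[nz]):
            raise AssertionError("nucleus pixels must lie in the cell of the same id")
        expected_cyt = np.where(nz, 0, cel)
        if not np.array_equal(cyt, expected_cyt):
            raise AssertionError("cytoplasm must equal cell minus nucleus, label-wise")
        mz = mit > 0
        if not np.array_equal(mit[mz], cyt[mz]):
            raise AssertionError("mitochondria must lie inside the same-id cytoplasm")
        for k in self.cells.ids():
            nuc_ids = np.unique(nuc[cel == k])
            nuc_ids = nuc_ids[nuc_ids > 0]
            if nuc_ids.size != 1 or nuc_ids[0] != k:
                raise AssertionError(f"cell {k} must contain exactly its own nucleus")


# ---------------------------------------------------------------------------
# Global thresholds
# ---------------------------------------------------------------------------

def threshold_otsu(img: IntensityImage) -> float:
    """Otsu global threshold maximizing between-class variance.

    Computed on the exact histogram of unique pixel values (no binning).
    The returned threshold is the midpoint between the optimal class
    boundary and the next distinct value, so it lies strictly inside
    (min, max) and classifies identically to the optimal split.
    """
    values, counts = np.unique(img.pixels, return_counts=True)
    if values.size < 2:
        raise ValueError("Otsu threshold undefined for a constant image")
    boundary = float(_skimage_otsu(hist=(counts, values)))
    k = int(np.searchsorted(values, boundary))
    return float(0.5 * (values[k] + values[min(k + 1, values.size - 1)]))


def threshold_min_cross_entropy(img: IntensityImage, correction_factor: float = 1.0) -> float:
    """Li's minimum cross-entropy global threshold, times a correction factor.

    The criterion for a candidate threshold t splitting the histogram
    into below (< t) and above (>= t) classes with value-sums S0, S1 and
    means mu0, mu1 is

        eta(t) = -(S0 * ln(mu0) + S1 * ln(mu1))

    (the value-entropy term common to all t is dropped). Every midpoint
    between consecutive unique values is scanned, so the minimizer is
    exact; the returned threshold is ``correction_factor`` times it.
    """
    if correction_factor <= 0:
        raise ValueError("correction_factor must be > 0")
    values, counts = np.unique(img.pixels, return_counts=True)
    if values.size < 2:
        raise ValueError("threshold undefined for a constant image")
    if values[0] <= 0:
        # Li's criterion takes logs of class means; shift is not meaningful
        # for fluorescence counts, so zero pixels are simply excluded from
        # the histogram (they carry no weight in the value sums anyway).
        counts = counts[values > 0]
        values = values[values > 0]
        if values.size < 2:
            raise ValueError("need >= 2 distinct positive values")
    weighted = values * counts
    cum_n = np.cumsum(counts)
    cum_s = np.cumsum(weighted)
    n_tot, s_tot = cum_n[-1], cum_s[-1]
    # candidate k: below-class = values[:k+1], i.e. t = midpoint(values[k], values[k+1])
    n0, s0 = cum_n[:-1], cum_s[:-1]
    n1, s1 = n_tot - n0, s_tot - s0
    mu0, mu1 = s0 / n0, s1 / n1
    eta = -(s0 * np.log(mu0) + s1 * np.log(mu1))
    k = int(np.argmin(eta))
    t_star = 0.5 * (values[k] + values[k + 1])
    return float(t_star * correction_factor)


# ---------------------------------------------------------------------------
# Seeded propagation
# ---------------------------------------------------------------------------

def propagate_cells(
    nuclei: LabelImage,
    guide: IntensityImage,
    foreground: np.ndarray | None = None,
    regularization: float = 0.05,
) -> LabelImage:
    """Assign foreground pixels to seeds by minimal geodesic cost.

    A step between 4-connected pixels p -> q costs
    sqrt(lambda^2 + (I(p) - I(q))^2) where I is the guide intensity and
    lambda = ``regularization``; the cost of a path is the sum of its
    steps. Each reachable foreground pixel takes the label of the seed
    with minimal total cost; exact ties go to the lower label id. Seeds
    keep their own labels, non-foreground pixels stay 0.
    """
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    if nuclei.shape != guide.shape:
        raise ValueError("nuclei and guide shapes differ")
    seeds = nuclei.labels
    if not np.any(seeds > 0):
        raise ValueError("seed image is empty")
    if foreground is None:
        fg = np.ones(seeds.shape, dtype=bool)
    else:
        fg = np.asarray(foreground, dtype=bool)
        if fg.shape != seeds.shape:
            raise ValueError("foreground and nuclei shapes differ")
        fg = fg | (seeds > 0)  # seeds are always foreground

    h, w = seeds.shape
    intens = guide.pixels.ravel()
    fg_flat = fg.ravel()
    seed_flat = seeds.ravel()
    out = np.zeros(h * w, dtype=np.int32)
    best = np.full(h * w, np.inf)
    lam2 = regularization * regularization

    # heap entries (cost, label, node): popping in (cost, label) order makes
    # the lower-label-wins tie rule automatic.
    heap: list[tuple[float, int, int]] = []
    seed_idx = np.flatnonzero(seed_flat > 0)
    for i in seed_idx:
        heap.append((0.0, int(seed_flat[i]), int(i)))
    heapq.heapify(heap)
    best[seed_idx] = 0.0

    push = heapq.heappush
    pop = heapq.heappop
    while heap:
        cost, label, i = pop(heap)
        if out[i]:
            continue
        out[i] = label
        row_start = (i // w) * w
        for j in (i - w, i + w, i - 1, i + 1):
            if j < 0 or j >= h * w or out[j] or not fg_flat[j]:
                continue
            if (j == i - 1 or j == i + 1) and (j // w) * w != row_start:
                continue  # row wrap
            di = intens[i] - intens[j]
            c = cost + float(np.sqrt(lam2 + di * di))
            if c < best[j]:
                best[j] = c
                push(heap, (c, label, j))

    labels = out.reshape(h, w)
    # Seeds own their pixels even if another seed's region surrounds them.
    labels[seeds > 0] = seeds[seeds > 0]
    return LabelImage(labels)


def derive_cytoplasm(cells: LabelImage, nuclei: LabelImage) -> LabelImage:
    """Cytoplasm(k) = cell(k) minus nucleus(k), labels preserved.

    A nucleus id with no matching cell id is an error; nucleus pixels
    falling outside their own cell are clipped (removed from nowhere —
    they simply do not subtract) after being reported via the raised
    warning counterpart in ``segment_cells``.
    """
    if cells.shape != nuclei.shape:
        raise ValueError("cells and nuclei shapes differ")
    cell_ids = set(cells.ids().tolist())
    missing = [int(k) for k in nuclei.ids() if int(k) not in cell_ids]
    if missing:
        raise ValueError(f"nucleus ids without a matching cell: {missing}")
    nz = nuclei.labels > 0
    n_stray = int(np.count_nonzero(nz & (nuclei.labels != cells.labels)))
    if n_stray:
        warnings.warn(
            f"{n_stray} nucleus pixels fall outside their own cell; clipped",
            stacklevel=2,
        )
    cyt = cells.labels.copy()
    cyt[nz] = 0
    return LabelImage(cyt)


def mask_mitochondria(
    cytoplasm: LabelImage,
    tmre: IntensityImage,
    spec: ThresholdSpec,
) -> tuple[LabelImage, list[int]]:
    """Gate the cytoplasm by a global TMRE threshold.

    mitochondria(k) = cytoplasm(k) ∩ {TMRE >= corrected threshold}.
    Returns the mask plus the ids of cells whose mitochondrial mask came
    out empty (flagged, not silently dropped).
    """
    if cytoplasm.shape != tmre.shape:
        raise ValueError("cytoplasm and TMRE shapes differ")
    thr = spec.resolve(tmre)
    mito = np.where(tmre.pixels >= thr, cytoplasm.labels, 0)
    present = set(np.unique(mito[mito > 0]).tolist())
    empty = [int(k) for k in cytoplasm.ids() if int(k) not in present]
    return LabelImage(mito), empty


def measure_compartments(labels: LabelImage, img: IntensityImage) -> pd.DataFrame:
    """Per-object pixel count, mean and integrated intensity.

    One row per nonzero label id; mean = integrated / count by
    construction. An empty label set yields an empty table.
    """
    if labels.shape != img.shape:
        raise ValueError("label and intensity shapes differ")
    ids = labels.ids()
    if ids.size == 0:
        return pd.DataFrame(columns=["object_id", "n_pixels", "mean", "integrated"])
    counts = ndimage.sum_labels(np.ones(img.shape), labels.labels, index=ids)
    integrated = ndimage.sum_labels(img.pixels, labels.labels, index=ids)
    return pd.DataFrame(
        {
            "object_id": ids.astype(int),
            "n_pixels": counts.astype(int),
            "mean": integrated / counts,
            "integrated": integrated,
        }
    )


# ---------------------------------------------------------------------------
# Composed pipeline step
# ---------------------------------------------------------------------------

def segment_cells(
    nuclei: LabelImage,
    guide: IntensityImage,
    tmre: IntensityImage,
    cell_threshold: ThresholdSpec | None = None,
    mito_threshold: ThresholdSpec | None = None,
    regularization: float = 0.05,
) -> tuple[SegmentationResult, list[int]]:
    """Full single-cell segmentation from nucleus seeds.

    The guide image (typically NAD(P)H) is thresholded to restrict the
    propagation to tissue foreground, cells are grown from the nuclei,
    cytoplasm is the per-cell set difference, and mitochondria are the
    cytoplasm pixels at or above the global corrected min-cross-entropy
    TMRE threshold. The threshold is computed on the TMRE image as
    given, with no additional smoothing, so punctate mitochondria are
    not blurred into their surroundings before gating. Returns the
    result and the ids of cells flagged for an empty mitochondrial
    mask.
    """
    cell_threshold = cell_threshold or ThresholdSpec(method="otsu")
    mito_threshold = mito_threshold or ThresholdSpec(
        method="min_cross_entropy", correction_factor=2.0
    )
    fg = guide.pixels >= cell_threshold.resolve(guide)
    cells = propagate_cells(nuclei, guide, foreground=fg, regularization=regularization)
    cytoplasm = derive_cytoplasm(cells, nuclei)
    mito, empty = mask_mitochondria(cytoplasm, tmre, mito_threshold)
    result = SegmentationResult(nuclei=nuclei, cells=cells, cytoplasm=cytoplasm, mitochondria=mito)
    return result, empty
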