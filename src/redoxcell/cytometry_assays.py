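"""Object colocalization counts and plate-reader assay reductions.

Colocalization: a DAPI nucleus is scored positive for a marker (Ki67,
proliferation; cleaved caspase 3, apoptosis) when its object overlaps a
marker object by at least a configurable fraction of its area (default:
any shared pixel). Percent positive = 100 * positives / nuclei.

Plate assays:
  * cell-growth percent of control — baseline-subtracted hemocytometer
    counts relative to control,
  * WST-1 viability — A450 minus A650 per well, media-blank corrected,
    percent of control,
  * CytoID autophagy — CytoID / Hoechst per well to correct for cell
    number,
  * senescence — percent X-gal positive cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_core import LabelImage

__all__ = [
    "ColocResult",
    "PlateWell",
    "percent_positive",
    "colocalization_summary",
    "cell_count_percent_of_control",
    "wst1_percent_viability",
    "cytoid_normalized",
    "senescence_percent",
    "wells_to_frame",
    "wells_from_frame",
]


@dataclass
class ColocResult:
    """Counts and percent-positive for the two IF markers."""

    n_dapi: int
    n_positive_ki67: int
    n_positive_cc3: int

    @property
    def pct_ki67(self) -> float:
        return 100.0 * self.n_positive_ki67 / self.n_dapi

    @property
    def pct_cc3(self) -> float:
        return 100.0 * self.n_positive_cc3 / self.n_dapi


@dataclass
class PlateWell:
    """One well of a plate assay.

    ``role`` is "sample", "blank" (no cells / media only) or "baseline"
    (pre-treatment reference, used by the cell-count assay). ``reads``
    holds the named raw measurements, e.g. a450/a650 for WST-1,
    cytoid/hoechst for the autophagy assay, or count for cell counts.
    """

    condition: str
    replicate: int
    role: str = "sample"
    reads: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ("sample", "blank", "baseline"):
            raise ValueError(f"unknown well role {self.role!r}")
        for name, v in self.reads.items():
            if v < 0:
                raise ValueError(f"read {name!r} must be >= 0, got {v}")


# ---------------------------------------------------------------------------
# Colocalization
# ---------------------------------------------------------------------------

def percent_positive(
    dapi: LabelImage,
    marker: LabelImage,
    min_overlap_fraction: float = 0.0,
) -> tuple[int, int, float]:
    """Count DAPI objects overlapping any marker object.

    With the default ``min_overlap_fraction`` of 0, one shared pixel
    suffices; a positive fraction requires that share of the DAPI
    object's area to be covered. Returns (n_dapi, n_positive, percent).
    """
    if dapi.shape != marker.shape:
        raise ValueError("DAPI and marker shapes differ")
    if not 0.0 <= min_overlap_fraction <= 1.0:
        raise ValueError("min_overlap_fraction must be in [0, 1]")
    ids = dapi.ids()
    if ids.size == 0:
        raise ValueError("no DAPI objects")
    marker_fg = (marker.labels > 0).astype(float)
    overlap = ndimage.sum_labels(marker_fg, dapi.labels, index=ids)
    if min_overlap_fraction == 0.0:
        positive = overlap >= 1
    else:
        area = ndimage.sum_labels(np.ones(dapi.shape), dapi.labels, index=ids)
        positive = overlap >= min_overlap_fraction * area
    n_pos = int(positive.sum())
    return int(ids.size), n_pos, 100.0 * n_pos / ids.size


def colocalization_summary(
    dapi: LabelImage,
    ki67: LabelImage,
    cc3: LabelImage,
    min_overlap_fraction: float = 0.0,
) -> ColocResult:
    """Score every DAPI object against both markers."""
    n, pos_ki67, _ = percent_positive(dapi, ki67, min_overlap_fraction)
    _, pos_cc3, _ = percent_positive(dapi, cc3, min_overlap_fraction)
    return ColocResult(n_dapi=n, n_positive_ki67=pos_ki67, n_positive_cc3=pos_cc3)


# ---------------------------------------------------------------------------
# Plate reductions
# ---------------------------------------------------------------------------

def cell_count_percent_of_control(
    post_counts: Mapping[str, Sequence[float]],
    baseline_counts: Sequence[float],
    control: str,
) -> dict[str, float]:
    """Baseline-subtracted cell growth as a percent of control.

    adjusted(well) = count(well) - mean(baseline);
    percent(cond) = 100 * mean(adjusted(cond)) / mean(adjusted(control)).
    Net cell loss gives negative percents; growth above control exceeds
    100 — both are meaningful, so no clamping.
    """
    baseline = np.asarray(baseline_counts, dtype=float)
    if baseline.size == 0:
        raise ValueError("baseline counts are empty")
    if control not in post_counts:
        raise ValueError(f"control condition {control!r} missing")
    base_mean = baseline.mean()
    adjusted = {
        cond: np.asarray(c, dtype=float) - base_mean for cond, c in post_counts.items()
    }
    ctrl_mean = adjusted[control].mean()
    if ctrl_mean <= 0:
        raise ValueError("control adjusted mean must be > 0")
    return {cond: 100.0 * vals.mean() / ctrl_mean for cond, vals in adjusted.items()}


def wst1_percent_viability(wells: Sequence[PlateWell], control: str) -> dict[str, float]:
    """WST-1 formazan viability as percent of control.

    Per well: signal = A450 - A650 (removes the phenol-red background of
    the medium); then the mean signal of the no-cell blank wells is
    subtracted. Condition value = mean corrected signal over replicate
    wells; percent = 100 * condition / control.
    """
    blanks = [w for w in wells if w.role == "blank"]
    samples = [w for w in wells if w.role == "sample"]
    if not blanks:
        raise ValueError("WST-1 reduction requires blank wells")
    if not samples:
        raise ValueError("no sample wells present")

    def signal(w: PlateWell) -> float:
        return w.reads["a450"] - w.reads["a650"]

    blank_level = float(np.mean([signal(w) for w in blanks]))
    corrected: dict[str, list[float]] = {}
    for w in samples:
        corrected.setdefault(w.condition, []).append(signal(w) - blank_level)
    if control not in corrected:
        raise ValueError(f"control condition {control!r} missing")
    ctrl = float(np.mean(corrected[control]))
    if ctrl <= 0:
        raise ValueError("corrected control mean must be > 0")
    return {cond: 100.0 * float(np.mean(v)) / ctrl for cond, v in corrected.items()}


def cytoid_normalized(wells: Sequence[PlateWell]) -> tuple[pd.DataFrame, dict[str, float]]:
    """CytoID autophagy signal normalized to Hoechst per well.

    Returns the per-well table (condition, replicate, value) and the
    per-condition means over replicate wells.
    """
    rows = []
    for w in wells:
        if w.role != "sample":
            continue
        hoechst = w.reads["hoechst"]
        if hoechst <= 0:
            raise ValueError(f"Hoechst read must be > 0 (condition {w.condition!r})")
        rows.append(
            {
                "condition": w.condition,
                "replicate": w.replicate,
                "value": w.reads["cytoid"] / hoechst,
            }
        )
    if not rows:
        raise ValueError("no sample wells present")
    table = pd.DataFrame(rows)
    means = table.groupby("condition")["value"].mean().to_dict()
    return table, means


def senescence_percent(positive: int, total: int) -> float:
    """Percent of X-gal (senescence) positive cells."""
    if total <= 0:
        raise ValueError("total cell count must be > 0")
    if not 0 <= positive <= total:
        raise ValueError("positive count must be in [0, total]")
    return 100.0 * positive / total


# ---------------------------------------------------------------------------
# Table round-trip
# ---------------------------------------------------------------------------

def wells_to_frame(wells: Sequence[PlateWell]) -> pd.DataFrame:
    """Flatten wells to the CSV layout (one column per read name)."""
    rows = []
    for w in wells:
        row = {"condition": w.condition, "replicate": w.replicate, "role": w.role}
        row.update(w.reads)
        rows.append(row)
    return pd.DataFrame(rows)


def wells_from_frame(df: pd.DataFrame) -> list[PlateWell]:
    meta = {"condition", "replicate", "role"}
    read_cols = [c for c in df.columns if c not in meta]
    wells = []
    for _, row in df.iterrows():
        reads = {c: float(row[c]) for c in read_cols if pd.notna(row[c])}
        wells.append(
            PlateWell(
                condition=str(row["condition"]),
                replicate=int(row["replicate"]),
                role=str(row["role"]),
                reads=reads,
            )
        )
    return wells
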