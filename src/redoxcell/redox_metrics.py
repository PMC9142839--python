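"""Optical redox ratio maps and per-cell summaries.

The optical redox ratio (ORR) is the NAD(P)H autofluorescence intensity
divided by the FAD intensity, ORR = I_NAD(P)H / I_FAD. It is unitless
and reports the oxidation-reduction state of the cell: the two
cofactors sit on opposite sides of electron transfer, so their
intensity ratio shifts with metabolic state.

Two per-cell conventions exist and are both emitted: the primary value
is the ratio of cytoplasmic means (robust to zero-FAD pixels), with the
mean of per-pixel ratios reported as an auxiliary column. Group-level
summaries normalize per-cell values to the control mean and tabulate
fold-changes of each variable against control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_core import IntensityImage, LabelImage

__all__ = [
    "RedoxCellRecord",
    "orr_map",
    "per_cell_redox",
    "normalize_to_control",
    "fold_change_table",
    "redox_records_to_frame",
]

FOLD_VARIABLES = ("i_nadph", "i_fad", "orr")


@dataclass
class RedoxCellRecord:
    """Per-cell cytoplasmic intensities and redox ratio.

    ``orr`` is the ratio of cytoplasmic means; ``orr_pixelwise`` the
    mean of per-pixel ratios over defined (FAD > 0) pixels.
    """

    cell_id: int
    i_nadph: float
    i_fad: float
    orr: float
    orr_pixelwise: float
    orr_normalized: float = np.nan


def orr_map(nadph: IntensityImage, fad: IntensityImage) -> np.ndarray:
    """Per-pixel ORR; pixels with FAD = 0 are NaN (undefined, excluded)."""
    if nadph.shape != fad.shape:
        raise ValueError("NAD(P)H and FAD shapes differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(fad.pixels > 0, nadph.pixels / fad.pixels, np.nan)
    return out


def per_cell_redox(
    cytoplasm: LabelImage,
    nadph: IntensityImage,
    fad: IntensityImage,
) -> tuple[list[RedoxCellRecord], list[int]]:
    """Cytoplasmic NAD(P)H/FAD means and ORR per cell.

    Cells whose cytoplasmic FAD mean is zero have no defined ratio and
    are excluded; their ids are returned alongside the records.
    """
    if cytoplasm.shape != nadph.shape or cytoplasm.shape != fad.shape:
        raise ValueError("label and intensity shapes differ")
    ids = cytoplasm.ids()
    records: list[RedoxCellRecord] = []
    excluded: list[int] = []
    if ids.size == 0:
        return records, excluded
    lab = cytoplasm.labels
    counts = ndimage.sum_labels(np.ones(lab.shape), lab, index=ids)
    sum_n = ndimage.sum_labels(nadph.pixels, lab, index=ids)
    sum_f = ndimage.sum_labels(fad.pixels, lab, index=ids)
    ratio = orr_map(nadph, fad)
    defined = np.isfinite(ratio)
    n_def = ndimage.sum_labels(defined.astype(float), lab, index=ids)
    sum_ratio = ndimage.sum_labels(np.where(defined, ratio, 0.0), lab, index=ids)
    for k, c, sn, sf, nd, sr in zip(ids, counts, sum_n, sum_f, n_def, sum_ratio):
        mean_f = sf / c
        if mean_f <= 0:
            excluded.append(int(k))
            continue
        records.append(
            RedoxCellRecord(
                cell_id=int(k),
                i_nadph=sn / c,
                i_fad=mean_f,
                orr=(sn / c) / mean_f,
                orr_pixelwise=(sr / nd) if nd > 0 else np.nan,
            )
        )
    return records, excluded


def normalize_to_control(
    values: Sequence[float] | np.ndarray,
    control_values: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Divide each value by the pooled control mean (control mean -> 1)."""
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise ValueError("control group is empty")
    ref = control.mean()
    if ref <= 0:
        raise ValueError(f"control mean must be > 0, got {ref}")
    return np.asarray(values, dtype=float) / ref


def fold_change_table(
    groups: Mapping[str, pd.DataFrame],
    control: str,
    variables: Sequence[str] = FOLD_VARIABLES,
) -> pd.DataFrame:
    """Fold-change of group means relative to control, per variable.

    ``groups`` maps condition label -> per-cell table containing the
    requested variable columns (as produced by
    :func:`redox_records_to_frame`). fold = group mean / control mean.
    """
    if control not in groups:
        raise ValueError(f"control condition {control!r} missing from groups")
    ctrl_means = {v: groups[control][v].mean() for v in variables}
    for v, m in ctrl_means.items():
        if not m > 0:
            raise ValueError(f"control mean of {v!r} must be > 0")
    rows = []
    for cond, table in groups.items():
        row = {"condition": cond}
        for v in variables:
            row[v] = table[v].mean() / ctrl_means[v]
        rows.append(row)
    return pd.DataFrame(rows).set_index("condition")


def redox_records_to_frame(
    records: list[RedoxCellRecord],
    control_records: list[RedoxCellRecord] | None = None,
) -> pd.DataFrame:
    """Tabulate records; if control records are given, add orr_normalized."""
    df = pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "i_nadph": r.i_nadph,
                "i_fad": r.i_fad,
                "orr": r.orr,
                "orr_pixelwise": r.orr_pixelwise,
            }
            for r in records
        ]
    )
    if control_records is not None and len(df):
        ctrl = [r.orr for r in control_records]
        df["orr_normalized"] = normalize_to_control(df["orr"].to_numpy(), ctrl)
    return df
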