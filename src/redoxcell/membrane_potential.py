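"""Mitochondrial membrane potential from TMRE compartment intensities.

TMRE is a cationic dye whose accumulation across the inner mitochondrial
membrane follows the Nernst relation in non-quenching mode. With
RT = 61.5 mV per decade at 37 degC (the Nernst slope 2.303*R*T/F), the
per-cell potential is

    delta_psi = -RT * log10(FI_m / FI_n)   [mV]

where FI_m is the mean mitochondrial TMRE intensity and FI_n the mean
nuclear TMRE intensity. The nucleus serves as the cytosolic reference
because TMRE equilibrates similarly in nucleus and cytosol, while the
cytoplasmic signal proper is contaminated by mitochondrial dye. A more
polarized (more negative) mitochondrion accumulates more dye, so larger
FI_m/FI_n means more negative delta_psi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging_core import IntensityImage
from .segmentation import SegmentationResult, measure_compartments

__all__ = [
    "PotentialConfig",
    "CellPotentialRecord",
    "nernst_potential",
    "potential_table",
    "records_to_frame",
]


@dataclass
class PotentialConfig:
    """Nernst slope in mV per tenfold concentration ratio (61.5 at 37 degC)."""

    rt: float = 61.5

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError("rt must be > 0")


@dataclass
class CellPotentialRecord:
    """Per-cell TMRE compartment means and the derived potential in mV."""

    cell_id: int
    fi_n: float
    fi_m: float
    fi_cyto: float
    fi_cell: float
    delta_psi: float


def nernst_potential(fi_m: float, fi_n: float, cfg: PotentialConfig | None = None) -> float:
    """delta_psi = -rt * log10(fi_m / fi_n), in mV."""
    cfg = cfg or PotentialConfig()
    if fi_m <= 0 or fi_n <= 0:
        raise ValueError(
            f"Nernst potential undefined for nonpositive intensities (fi_m={fi_m}, fi_n={fi_n})"
        )
    return float(-cfg.rt * np.log10(fi_m / fi_n))


def potential_table(
    seg: SegmentationResult,
    tmre: IntensityImage,
    cfg: PotentialConfig | None = None,
) -> tuple[list[CellPotentialRecord], list[int]]:
    """Per-cell membrane potential from a segmentation and the TMRE image.

    Compartment intensities are means (size-invariant, as the Nernst
    ratio compares concentrations). Cells with an empty nuclear or
    mitochondrial mask, or a nonpositive compartment mean, cannot yield
    a defined potential; they are excluded and their ids returned.
    """
    cfg = cfg or PotentialConfig()
    if seg.cells.shape != tmre.shape:
        raise ValueError("segmentation and TMRE shapes differ")
    tables = {
        name: measure_compartments(getattr(seg, name), tmre).set_index("object_id")
        for name in ("nuclei", "cells", "cytoplasm", "mitochondria")
    }
    records: list[CellPotentialRecord] = []
    excluded: list[int] = []
    for k in seg.cells.ids():
        k = int(k)
        if k not in tables["nuclei"].index or k not in tables["mitochondria"].index:
            excluded.append(k)
            continue
        fi_n = float(tables["nuclei"].loc[k, "mean"])
        fi_m = float(tables["mitochondria"].loc[k, "mean"])
        if fi_n <= 0 or fi_m <= 0:
            excluded.append(k)
            continue
        fi_cyto = float(tables["cytoplasm"].loc[k, "mean"]) if k in tables["cytoplasm"].index else np.nan
        fi_cell = float(tables["cells"].loc[k, "mean"])
        records.append(
            CellPotentialRecord(
                cell_id=k,
                fi_n=fi_n,
                fi_m=fi_m,
                fi_cyto=fi_cyto,
                fi_cell=fi_cell,
                delta_psi=nernst_potential(fi_m, fi_n, cfg),
            )
        )
    return records, excluded


def records_to_frame(records: list[CellPotentialRecord]) -> pd.DataFrame:
    """Tabulate records with the CSV column layout (delta_psi in mV)."""
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "fi_n": r.fi_n,
                "fi_m": r.fi_m,
                "fi_cyto": r.fi_cyto,
                "fi_cell": r.fi_cell,
                "delta_psi_mV": r.delta_psi,
            }
            for r in records
        ]
    )
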