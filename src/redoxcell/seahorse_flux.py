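"""Extracellular-flux (mito stress test) trace model and metrics.

A mito stress test measures the oxygen consumption rate (OCR, pmol
O2/min) and extracellular acidification rate (ECAR, mpH/min) of a well
over repeated measurement cycles: three baseline cycles, then three
cycles after each sequential injection of oligomycin (ATP-synthase
inhibitor), FCCP (uncoupler) and rotenone + antimycin A (electron
transport chain shutdown). Rates are normalized to DNA content per well
via crystal-violet absorbance.

Metrics:
  * basal respiration = mean baseline OCR - mean OCR after
    rotenone/antimycin A (the non-mitochondrial floor),
  * OCR:ECAR ratio at baseline — oxidative vs glycolytic balance,
  * energy-phenotype quadrant relative to control baseline means
    (aerobic / quiescent / energetic / glycolytic),
  * optional derived metrics (ATP-linked, maximal, spare capacity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AGENTS",
    "FluxTrace",
    "FluxMetrics",
    "normalize_flux",
    "basal_respiration",
    "ocr_ecar_ratio",
    "energetic_quadrant",
    "atp_linked_respiration",
    "maximal_respiration",
    "spare_capacity",
    "traces_to_frames",
    "traces_from_frames",
    "read_traces_csv",
    "write_traces_csv",
]

AGENTS = ("oligomycin", "FCCP", "rotenone_antimycinA")


@dataclass
class FluxTrace:
    """One well's OCR/ECAR cycles with the injection schedule.

    ``injections`` lists (last cycle index of the preceding phase,
    agent): the standard layout has cycles 0-2 baseline and injections
    after cycles 2, 5 and 8. ``dna_absorbance`` is the crystal-violet
    A590 normalizer.
    """

    well: str
    condition: str
    times: np.ndarray
    ocr: np.ndarray
    ecar: np.ndarray
    injections: list[tuple[int, str]] = field(
        default_factory=lambda: [(2, "oligomycin"), (5, "FCCP"), (8, "rotenone_antimycinA")]
    )
    dna_absorbance: float = 1.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        self.ecar = np.asarray(self.ecar, dtype=float)
        n = self.times.size
        if self.ocr.size != n or self.ecar.size != n:
            raise ValueError("times, ocr, ecar must have equal length")
        if n >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("cycle times must be strictly increasing")
        for idx, agent in self.injections:
            if agent not in AGENTS:
                raise ValueError(f"unknown agent {agent!r}")
            if not 0 <= idx < n - 1:
                raise ValueError(f"injection index {idx} leaves no post-injection cycles")
        if sorted(i for i, _ in self.injections) != [i for i, _ in self.injections]:
            raise ValueError("injections must be in cycle order")

    @property
    def n_cycles(self) -> int:
        return self.times.size

    def phase_slices(self) -> list[slice]:
        """Cycle ranges for baseline and each post-injection phase."""
        bounds = [i for i, _ in self.injections]
        starts = [0] + [b + 1 for b in bounds]
        ends = bounds + [self.n_cycles - 1]
        return [slice(s, e + 1) for s, e in zip(starts, ends)]

    def phase_of(self, agent: str) -> slice:
        """Cycles following the named injection (until the next one)."""
        for phase_idx, (_, a) in enumerate(self.injections):
            if a == agent:
                return self.phase_slices()[phase_idx + 1]
        raise ValueError(f"trace has no {agent!r} injection")


@dataclass
class FluxMetrics:
    """Summary metrics for one well (quadrant relative to a stated control)."""

    well: str
    condition: str
    basal_respiration: float
    ocr_ecar_ratio: float
    quadrant: str | None = None


def normalize_flux(trace: FluxTrace) -> FluxTrace:
    """Divide every OCR/ECAR cycle by the well's crystal-violet A590."""
    if trace.dna_absorbance <= 0:
        raise ValueError("dna_absorbance must be > 0")
    return replace(
        trace,
        ocr=trace.ocr / trace.dna_absorbance,
        ecar=trace.ecar / trace.dna_absorbance,
        normalized=True,
    )


def _baseline_ocr(trace: FluxTrace) -> np.ndarray:
    return trace.ocr[trace.phase_slices()[0]]


def basal_respiration(trace: FluxTrace) -> float:
    """Mean baseline OCR minus the post-rotenone/antimycin-A mean.

    The residual OCR after electron-transport shutdown is
    non-mitochondrial; subtracting it isolates basal mitochondrial
    respiration.
    """
    post = trace.ocr[trace.phase_of("rotenone_antimycinA")]
    return float(_baseline_ocr(trace).mean() - post.mean())


def ocr_ecar_ratio(trace: FluxTrace) -> float:
    """Mean baseline OCR / mean baseline ECAR."""
    base = trace.phase_slices()[0]
    ecar = trace.ecar[base].mean()
    if ecar <= 0:
        raise ValueError("baseline ECAR mean must be > 0")
    return float(trace.ocr[base].mean() / ecar)


def energetic_quadrant(
    ocr: float, ecar: float, control_ocr: float, control_ecar: float
) -> str:
    """Energy-phenotype quadrant relative to the control's baseline means.

    energetic: both above control; aerobic: only OCR above;
    glycolytic: only ECAR above; quiescent: neither above (points
    exactly on the control boundary count as not-above).
    """
    if control_ocr <= 0 or control_ecar <= 0:
        raise ValueError("control references must be > 0")
    high_ocr, high_ecar = ocr > control_ocr, ecar > control_ecar
    if high_ocr and high_ecar:
        return "energetic"
    if high_ocr:
        return "aerobic"
    if high_ecar:
        return "glycolytic"
    return "quiescent"


def atp_linked_respiration(trace: FluxTrace) -> float:
    """Baseline OCR mean minus post-oligomycin mean (ATP-synthase linked)."""
    return float(_baseline_ocr(trace).mean() - trace.ocr[trace.phase_of("oligomycin")].mean())


def maximal_respiration(trace: FluxTrace) -> float:
    """Post-FCCP OCR mean minus the non-mitochondrial floor."""
    post_fccp = trace.ocr[trace.phase_of("FCCP")].mean()
    floor = trace.ocr[trace.phase_of("rotenone_antimycinA")].mean()
    return float(post_fccp - floor)


def spare_capacity(trace: FluxTrace) -> float:
    """Maximal minus basal respiration."""
    return maximal_respiration(trace) - basal_respiration(trace)


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def traces_to_frames(traces: Sequence[FluxTrace]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(cycles table, injections table) in the on-disk CSV layout."""
    cyc_rows, inj_rows = [], []
    for t in traces:
        for c in range(t.n_cycles):
            cyc_rows.append(
                {
                    "well": t.well,
                    "condition": t.condition,
                    "cycle": c,
                    "time_min": t.times[c],
                    "ocr": t.ocr[c],
                    "ecar": t.ecar[c],
                    "dna_absorbance": t.dna_absorbance,
                }
            )
        for idx, agent in t.injections:
            inj_rows.append({"well": t.well, "after_cycle": idx, "agent": agent})
    return pd.DataFrame(cyc_rows), pd.DataFrame(inj_rows)


def traces_from_frames(cycles: pd.DataFrame, injections: pd.DataFrame) -> list[FluxTrace]:
    traces = []
    for well, grp in cycles.groupby("well", sort=False):
        grp = grp.sort_values("cycle")
        inj = injections[injections["well"] == well].sort_values("after_cycle")
        traces.append(
            FluxTrace(
                well=str(well),
                condition=str(grp["condition"].iloc[0]),
                times=grp["time_min"].to_numpy(),
                ocr=grp["ocr"].to_numpy(),
                ecar=grp["ecar"].to_numpy(),
                injections=[(int(r.after_cycle), str(r.agent)) for r in inj.itertuples()],
                dna_absorbance=float(grp["dna_absorbance"].iloc[0]),
            )
        )
    return traces


def write_traces_csv(traces: Sequence[FluxTrace], cycles_path: str | Path, injections_path: str | Path) -> None:
    cycles, injections = traces_to_frames(traces)
    cycles.to_csv(cycles_path, index=False)
    injections.to_csv(injections_path, index=False)


def read_traces_csv(cycles_path: str | Path, injections_path: str | Path) -> list[FluxTrace]:
    return traces_from_frames(pd.read_csv(cycles_path), pd.read_csv(injections_path))
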