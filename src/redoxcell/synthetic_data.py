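"""Ground-truth generators for every input the analysis consumes.

The generators emulate the image-formation and assay structure the
pipeline expects, with all true values recorded before noise so that
parameter-recovery tests can compare pipeline output against the
configured ground truth:

  * cell scenes — non-overlapping elliptical cells with nucleus,
    cytoplasm and punctate mitochondrial compartments; channel
    intensities proportional to fluorophore amount with Poisson shot
    noise (autofluorescence is photon counting); TMRE set by inverting
    the Nernst relation, FI_m = FI_n * 10^(-delta_psi/RT); an
    extracellular TMRE background models the unwashed free dye in the
    medium (cells load over medium by roughly the plasma-membrane
    Nernst factor);
  * photon-count decay stacks for the NAD(P)H and FAD channels whose
    temporal integral reproduces the channel intensity;
  * mito-stress flux traces — 12 cycles (baseline + three cycles after
    each of oligomycin, FCCP, rotenone/antimycin A) with Gaussian cycle
    noise and a crystal-violet DNA normalizer per well;
  * plate tables (WST-1, CytoID, cell counts) with replicate wells,
    blanks and baseline wells;
  * normal group samples for the statistics stage.

All generators take an explicit seed and never touch global random
state; the same config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cytometry_assays import PlateWell
from .imaging_core import DecayStack, IntensityImage, LabelImage
from .seahorse_flux import FluxTrace
from .stats_report import GroupSample

__all__ = [
    "SimConfig",
    "SimScene",
    "generate_cell_scene",
    "generate_coloc_scene",
    "generate_flux_trace",
    "generate_plate_table",
    "generate_group_samples",
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    Imaging intensities are expected photon counts per pixel per frame.
    The TMRE landscape (cytosol = nucleus, medium background from
    unwashed dye) and the mitochondrial puncta geometry are chosen so
    that a global corrected threshold can separate medium, cytosol and
    mitochondria, as the imaging protocol requires.
    """

    seed: int = 0
    image_size: int = 448
    n_cells: int = 200
    nucleus_radius: tuple[float, float] = (3.5, 4.5)
    cell_radius: tuple[float, float] = (8.0, 11.0)

    # channel baselines (expected photons / pixel)
    nadph_baseline: float = 30.0
    fad_baseline: float = 25.0
    nucleus_dim_fraction: float = 0.5  # cofactor signal in nucleus vs cytoplasm
    tmre_nuclear: float = 15.0         # nuclear = cytosolic TMRE level
    tmre_background: float = 3.5       # unwashed free dye in the medium
    background: float = 1.0            # autofluorescence background (cofactor channels)

    # per-condition effects
    nadph_fold: float = 1.0
    fad_fold: float = 1.0
    delta_psi_mv: float = -61.5
    rt_mv: float = 61.5

    # mitochondria
    puncta_per_cell: int = 6
    puncta_radius: float = 2.0

    # decay stacks
    n_decay_bins: int = 8
    decay_rate_nadph: float = 0.45  # per-bin exponential decay constants
    decay_rate_fad: float = 0.60

    # flux traces (levels are DNA-normalized rates)
    flux_basal: float = 100.0
    flux_post_oligomycin: float = 40.0
    flux_post_fccp: float = 160.0
    flux_floor: float = 20.0
    ecar_baseline: float = 30.0
    ecar_phase_factors: tuple[float, float, float, float] = (1.0, 1.3, 1.1, 0.8)
    flux_noise_frac: float = 0.02   # cycle noise sigma as fraction of basal
    flux_n_wells: int = 6
    cycle_minutes: float = 6.0
    dna_absorbance_mean: float = 1.0
    dna_absorbance_sd: float = 0.05

    # plate assays
    plate_noise_frac: float = 0.03
    n_replicates: int = 6

    def __post_init__(self) -> None:
        if self.nadph_fold <= 0 or self.fad_fold <= 0:
            raise ValueError("channel folds must be > 0")
        if not 0 < self.nucleus_radius[0] <= self.nucleus_radius[1]:
            raise ValueError("nucleus radius range must be positive and ordered")
        if not 0 < self.cell_radius[0] <= self.cell_radius[1]:
            raise ValueError("cell radius range must be positive and ordered")
        if self.nucleus_radius[1] >= self.cell_radius[0]:
            raise ValueError("nucleus radius must be smaller than cell radius")
        if self.rt_mv <= 0:
            raise ValueError("rt_mv must be > 0")

    @property
    def tmre_ratio(self) -> float:
        """Ground-truth FI_m / FI_n implied by the configured potential."""
        return 10.0 ** (-self.delta_psi_mv / self.rt_mv)


@dataclass
class SimScene:
    """Generated images plus the ground truth they were built from."""

    config: SimConfig
    images: dict[str, IntensityImage]
    decays: dict[str, DecayStack]
    nuclei: LabelImage
    cells: LabelImage
    cytoplasm: LabelImage
    mitochondria: LabelImage
    truth: pd.DataFrame  # per-cell true means: fi_n, fi_m, i_nadph, i_fad, orr, delta_psi


def _ellipse_mask(shape, center, a, b, theta):
    """Boolean mask of a rotated ellipse, evaluated on a local window."""
    cy, cx = center
    r = int(np.ceil(max(a, b))) + 1
    y0, y1 = max(0, int(cy) - r), min(shape[0], int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(shape[1], int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (slice(y0, y1), slice(x0, x1)), (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_cell_scene(cfg: SimConfig) -> SimScene:
    """Render one field of view with known per-cell ground truth.

    Cells are placed on a jittered grid so the requested count always
    packs without overlap; each is an ellipse with a concentric
    elliptical nucleus and disk-shaped mitochondrial puncta sampled
    inside its cytoplasm. Expected intensities are constant per
    compartment; the emitted images carry Poisson noise while the
    ground-truth table records the noiseless means.
    """
    rng = np.random.default_rng(cfg.seed)
    size = cfg.image_size
    n = cfg.n_cells
    grid = int(np.ceil(np.sqrt(n)))
    spacing = size / grid
    max_r = cfg.cell_radius[1]
    jitter = max(0.0, spacing / 2 - max_r - 1.0)
    if spacing / 2 < max_r + 1.0:
        raise ValueError(
            f"cannot pack {n} cells of radius {max_r} into a {size}x{size} image"
        )

    shape = (size, size)
    nuclei = np.zeros(shape, dtype=np.int32)
    cells = np.zeros(shape, dtype=np.int32)
    mito = np.zeros(shape, dtype=np.int32)

    slots = [(i, j) for i in range(grid) for j in range(grid)]
    slots = [slots[k] for k in rng.permutation(len(slots))[:n]]

    ratio = cfg.tmre_ratio
    rows = []
    for label, (gi, gj) in enumerate(slots, start=1):
        cy = (gi + 0.5) * spacing + rng.uniform(-jitter, jitter)
        cx = (gj + 0.5) * spacing + rng.uniform(-jitter, jitter)
        a = rng.uniform(*cfg.cell_radius)
        b = rng.uniform(*cfg.cell_radius)
        na = rng.uniform(*cfg.nucleus_radius)
        nb = rng.uniform(*cfg.nucleus_radius)
        theta = rng.uniform(0, np.pi)
        win, cell_m = _ellipse_mask(shape, (cy, cx), a, b, theta)
        cells[win][cell_m] = label
        nwin, nuc_m = _ellipse_mask(shape, (cy, cx), na, nb, theta)
        nuclei[nwin][nuc_m] = label

        # puncta sampled in this cell's cytoplasm, clipped to it
        cyto_mask = (cells == label) & (nuclei != label)
        ys, xs = np.nonzero(cyto_mask)
        if ys.size:
            picks = rng.choice(ys.size, size=min(cfg.puncta_per_cell, ys.size), replace=False)
            for p in picks:
                pwin, pm = _ellipse_mask(
                    shape, (float(ys[p]), float(xs[p])), cfg.puncta_radius, cfg.puncta_radius, 0.0
                )
                sub = mito[pwin]
                sub[pm & cyto_mask[pwin]] = label

        rows.append(
            {
                "cell_id": label,
                "fi_n": cfg.tmre_nuclear,
                "fi_m": cfg.tmre_nuclear * ratio,
                "i_nadph": cfg.nadph_baseline * cfg.nadph_fold,
                "i_fad": cfg.fad_baseline * cfg.fad_fold,
                "orr": (cfg.nadph_baseline * cfg.nadph_fold) / (cfg.fad_baseline * cfg.fad_fold),
                "delta_psi": cfg.delta_psi_mv,
            }
        )

    cyto = np.where(nuclei > 0, 0, cells)
    in_nuc, in_cyto = nuclei > 0, cyto > 0

    def compartment_image(nuc_level, cyto_level, bg_level):
        img = np.full(shape, bg_level, dtype=float)
        img[in_cyto] = cyto_level
        img[in_nuc] = nuc_level
        return img

    nadph_level = cfg.nadph_baseline * cfg.nadph_fold
    fad_level = cfg.fad_baseline * cfg.fad_fold
    expected = {
        "NADPH": compartment_image(
            cfg.nucleus_dim_fraction * nadph_level, nadph_level, cfg.background
        ),
        "FAD": compartment_image(
            cfg.nucleus_dim_fraction * fad_level, fad_level, cfg.background
        ),
        "TMRE": compartment_image(cfg.tmre_nuclear, cfg.tmre_nuclear, cfg.tmre_background),
    }
    expected["TMRE"][mito > 0] = cfg.tmre_nuclear * ratio

    images = {
        ch: IntensityImage(rng.poisson(exp).astype(float), channel=ch)
        for ch, exp in expected.items()
    }

    decays = {}
    for ch, rate in (("NADPH", cfg.decay_rate_nadph), ("FAD", cfg.decay_rate_fad)):
        w = np.exp(-rate * np.arange(cfg.n_decay_bins))
        w /= w.sum()
        lam = expected[ch][None, :, :] * w[:, None, None]
        decays[ch] = DecayStack(rng.poisson(lam), channel=ch)

    return SimScene(
        config=cfg,
        images=images,
        decays=decays,
        nuclei=LabelImage(nuclei),
        cells=LabelImage(cells),
        cytoplasm=LabelImage(cyto),
        mitochondria=LabelImage(mito),
        truth=pd.DataFrame(rows),
    )


def generate_coloc_scene(
    n_nuclei: int,
    n_ki67: int,
    n_cc3: int,
    seed: int = 0,
    image_size: int = 256,
    nucleus_radius: float = 4.0,
) -> tuple[LabelImage, LabelImage, LabelImage]:
    """DAPI/Ki67/CC3 label images with exact configured overlap counts.

    The first ``n_ki67`` nuclei receive an overlapping Ki67 object and
    the last ``n_cc3`` an overlapping CC3 object (a nucleus may carry
    both); remaining nuclei stay marker-free, so the ground-truth
    percent positive is exactly 100*n_marker/n_nuclei.
    """
    if not (0 <= n_ki67 <= n_nuclei and 0 <= n_cc3 <= n_nuclei):
        raise ValueError("marker counts must be within [0, n_nuclei]")
    rng = np.random.default_rng(seed)
    grid = int(np.ceil(np.sqrt(n_nuclei)))
    spacing = image_size / grid
    if spacing / 2 < 2 * nucleus_radius + 2:
        raise ValueError("nuclei too large to keep marker objects from bridging")
    shape = (image_size, image_size)
    dapi = np.zeros(shape, dtype=np.int32)
    ki67 = np.zeros(shape, dtype=np.int32)
    cc3 = np.zeros(shape, dtype=np.int32)
    slots = [(i, j) for i in range(grid) for j in range(grid)]
    slots = [slots[k] for k in rng.permutation(len(slots))[:n_nuclei]]
    for label, (gi, gj) in enumerate(slots, start=1):
        cy, cx = (gi + 0.5) * spacing, (gj + 0.5) * spacing
        win, m = _ellipse_mask(shape, (cy, cx), nucleus_radius, nucleus_radius, 0.0)
        dapi[win][m] = label
        off = nucleus_radius / 2
        if label <= n_ki67:
            w2, m2 = _ellipse_mask(shape, (cy + off, cx), nucleus_radius, nucleus_radius, 0.0)
            ki67[w2][m2] = label
        if label > n_nuclei - n_cc3:
            w3, m3 = _ellipse_mask(shape, (cy - off, cx), nucleus_radius, nucleus_radius, 0.0)
            cc3[w3][m3] = label
    return LabelImage(dapi), LabelImage(ki67), LabelImage(cc3)


def generate_flux_trace(
    cfg: SimConfig, condition: str = "control", n_wells: int | None = None
) -> list[FluxTrace]:
    """Mito-stress traces: 12 cycles, injections after cycles 2, 5, 8.

    OCR phase levels are (basal, post-oligomycin, post-FCCP, floor) and
    ECAR levels the baseline times the configured phase factors; both
    get Gaussian cycle noise with sigma = ``flux_noise_frac`` times the
    basal (resp. baseline ECAR) level. Raw rates are the normalized
    levels multiplied by the well's crystal-violet absorbance, so
    normalization recovers the configured levels.
    """
    rng = np.random.default_rng(cfg.seed)
    n_wells = cfg.flux_n_wells if n_wells is None else n_wells
    ocr_levels = np.repeat(
        [cfg.flux_basal, cfg.flux_post_oligomycin, cfg.flux_post_fccp, cfg.flux_floor], 3
    )
    ecar_levels = np.repeat(cfg.ecar_baseline * np.asarray(cfg.ecar_phase_factors), 3)
    times = cfg.cycle_minutes * np.arange(1, 13)
    sigma_ocr = cfg.flux_noise_frac * cfg.flux_basal
    sigma_ecar = cfg.flux_noise_frac * cfg.ecar_baseline
    traces = []
    for w in range(n_wells):
        dna = max(1e-6, rng.normal(cfg.dna_absorbance_mean, cfg.dna_absorbance_sd))
        ocr = ocr_levels + rng.normal(0.0, sigma_ocr, size=12) if sigma_ocr > 0 else ocr_levels.astype(float)
        ecar = ecar_levels + rng.normal(0.0, sigma_ecar, size=12) if sigma_ecar > 0 else ecar_levels.astype(float)
        traces.append(
            FluxTrace(
                well=f"{condition}_{w + 1}",
                condition=condition,
                times=times,
                ocr=np.clip(ocr, 0, None) * dna,
                ecar=np.clip(ecar, 0, None) * dna,
                dna_absorbance=dna,
            )
        )
    return traces


def generate_plate_table(
    cfg: SimConfig,
    assay: str = "wst1",
    condition_levels: Mapping[str, float] | None = None,
) -> list[PlateWell]:
    """Replicate plate wells for one assay.

    assay="wst1":   ``condition_levels`` are true blank-corrected
                    formazan signals (A450-A650 scale); blank wells and
                    the phenol-red A650 background are included.
    assay="counts": levels are true post-treatment cell counts;
                    baseline wells at the configured baseline count are
                    included under role "baseline".
    assay="cytoid": levels are true CytoID/Hoechst ratios; each well
                    gets a Hoechst read and a matching CytoID read.
    """
    rng = np.random.default_rng(cfg.seed)
    wells: list[PlateWell] = []
    noise = cfg.plate_noise_frac
    if assay == "wst1":
        levels = condition_levels or {"control": 0.80, "treated": 0.53}
        a650, blank_level = 0.08, 0.05
        for r in range(cfg.n_replicates):
            wells.append(
                PlateWell(
                    condition="blank",
                    replicate=r + 1,
                    role="blank",
                    reads={
                        "a450": a650 + blank_level * (1 + rng.normal(0, noise)),
                        "a650": a650,
                    },
                )
            )
        for cond, level in levels.items():
            for r in range(cfg.n_replicates):
                sig = blank_level + level * (1 + rng.normal(0, noise))
                wells.append(
                    PlateWell(
                        condition=cond,
                        replicate=r + 1,
                        role="sample",
                        reads={"a450": a650 + sig, "a650": a650},
                    )
                )
    elif assay == "counts":
        levels = condition_levels or {"control": 300.0, "treated": 232.0}
        baseline = 100.0
        for r in range(cfg.n_replicates):
            wells.append(
                PlateWell(
                    condition="baseline",
                    replicate=r + 1,
                    role="baseline",
                    reads={"count": max(0.0, baseline * (1 + rng.normal(0, noise)))},
                )
            )
        for cond, level in levels.items():
            for r in range(cfg.n_replicates):
                wells.append(
                    PlateWell(
                        condition=cond,
                        replicate=r + 1,
                        role="sample",
                        reads={"count": max(0.0, level * (1 + rng.normal(0, noise)))},
                    )
                )
    elif assay == "cytoid":
        levels = condition_levels or {"control": 1.0, "treated": 1.4}
        hoechst_mean = 2000.0
        for cond, level in levels.items():
            for r in range(cfg.n_replicates):
                hoechst = max(1.0, hoechst_mean * (1 + rng.normal(0, noise)))
                wells.append(
                    PlateWell(
                        condition=cond,
                        replicate=r + 1,
                        role="sample",
                        reads={
                            "hoechst": hoechst,
                            "cytoid": hoechst * level * (1 + rng.normal(0, noise)),
                        },
                    )
                )
    else:
        raise ValueError(f"unknown assay {assay!r}")
    return wells


def generate_group_samples(
    effect_sizes: Mapping[str, float],
    n: int,
    seed: int = 0,
    sd: float = 1.0,
) -> list[GroupSample]:
    """Normal samples, one group per label, with the configured means."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    return [
        GroupSample(label=label, values=rng.normal(mean, sd, size=n))
        for label, mean in effect_sizes.items()
    ]
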