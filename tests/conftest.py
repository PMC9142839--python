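import numpy as np
import pytest

from redoxcell import (
    SimConfig,
    generate_cell_scene,
    integrate_decay,
    per_cell_redox,
    potential_table,
    segment_cells,
)
from redoxcell.redox_metrics import redox_records_to_frame


@pytest.fixture(scope="session")
def small_scene():
    """A compact 9-cell field of view used by many structural tests."""
    return generate_cell_scene(SimConfig(seed=7, image_size=128, n_cells=9))


@pytest.fixture(scope="session")
def small_segmentation(small_scene):
    guide = integrate_decay(small_scene.decays["NADPH"], 1)
    seg, empty = segment_cells(small_scene.nuclei, guide, small_scene.images["TMRE"])
    return seg, empty


def run_redox_condition(seed: int, nadph_fold: float, fad_fold: float):
    """Full pipeline (decay integration -> segmentation -> per-cell ORR)."""
    cfg = SimConfig(seed=seed, nadph_fold=nadph_fold, fad_fold=fad_fold)
    scene = generate_cell_scene(cfg)
    nadph = integrate_decay(scene.decays["NADPH"], 1)
    fad = integrate_decay(scene.decays["FAD"], 1)
    seg, _ = segment_cells(scene.nuclei, nadph, scene.images["TMRE"])
    seg.validate()
    records, _ = per_cell_redox(seg.cytoplasm, nadph, fad)
    return redox_records_to_frame(records)


@pytest.fixture(scope="session")
def fold_study_frames():
    """Control vs treated scenes with NAD(P)H x1.70 and FAD x1.99 (200 cells each)."""
    control = run_redox_condition(1, 1.0, 1.0)
    treated = run_redox_condition(2, 1.70, 1.99)
    return control, treated


def recover_delta_psi(target_mv: float, seed: int = 1):
    """Median pipeline potential for a scene generated at the target."""
    cfg = SimConfig(seed=seed, image_size=352, n_cells=120, delta_psi_mv=target_mv)
    scene = generate_cell_scene(cfg)
    guide = integrate_decay(scene.decays["NADPH"], 1)
    seg, _ = segment_cells(scene.nuclei, guide, scene.images["TMRE"])
    seg.validate()
    records, _ = potential_table(seg, scene.images["TMRE"])
    return float(np.median([r.delta_psi for r in records])), len(records)


@pytest.fixture(scope="session")
def delta_psi_recovery():
    """Median recovered potential for the three configured targets."""
    targets = (-30.0, -61.5, -120.0)
    return {t: recover_delta_psi(t) for t in targets}
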