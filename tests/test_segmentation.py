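import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as csgraph_dijkstra

from redoxcell.imaging_core import IntensityImage, LabelImage
from redoxcell.segmentation import (
    SegmentationResult,
    ThresholdSpec,
    derive_cytoplasm,
    mask_mitochondria,
    measure_compartments,
    propagate_cells,
    threshold_min_cross_entropy,
    threshold_otsu,
)

# ---------------------------------------------------------------------------
# Brute-force threshold oracles
# ---------------------------------------------------------------------------

def otsu_oracle(values: np.ndarray) -> float:
    """Exhaustive between-class-variance maximization over unique values.

    Returns the midpoint between the optimal class boundary and the next
    distinct value (the strictly interior threshold convention).
    """
    uniq = np.unique(values)
    best_k, best_s = None, -np.inf
    for k, t in enumerate(uniq[:-1]):
        lo, hi = values[values <= t], values[values > t]
        s = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if s > best_s:
            best_s, best_k = s, k
    return float(0.5 * (uniq[best_k] + uniq[best_k + 1]))


def li_oracle(values: np.ndarray) -> float:
    """Exhaustive minimum-cross-entropy scan over unique-value midpoints."""
    uniq = np.unique(values[values > 0])
    best_t, best_e = None, np.inf
    for k in range(uniq.size - 1):
        t = 0.5 * (uniq[k] + uniq[k + 1])
        lo, hi = values[(values > 0) & (values < t)], values[values >= t]
        eta = -(lo.sum() * np.log(lo.mean()) + hi.sum() * np.log(hi.mean()))
        if eta < best_e:
            best_e, best_t = eta, t
    return float(best_t)


def random_histogram(rng) -> np.ndarray:
    n_levels = rng.integers(2, 8)
    levels = rng.choice(np.arange(1, 60), size=n_levels, replace=False)
    counts = rng.integers(1, 30, size=n_levels)
    return np.repeat(levels, counts).astype(float)


class TestThresholds:
    def test_otsu_bimodal_lies_between_modes(self):
        img = IntensityImage(np.repeat([10.0, 100.0], 50).reshape(10, 10))
        t = threshold_otsu(img)
        assert 10 < t < 100

    def test_otsu_constant_image_rejected(self):
        with pytest.raises(ValueError):
            threshold_otsu(IntensityImage(np.full((4, 4), 5.0)))

    def test_otsu_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            vals = random_histogram(rng)
            img = IntensityImage(vals.reshape(1, -1))
            assert threshold_otsu(img) == pytest.approx(otsu_oracle(vals))

    def test_li_bimodal_lies_between_modes(self):
        img = IntensityImage(np.repeat([10.0, 100.0], 50).reshape(10, 10))
        t = threshold_min_cross_entropy(img, 1.0)
        assert 10 < t < 100

    def test_li_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            vals = random_histogram(rng)
            img = IntensityImage(vals.reshape(1, -1))
            assert threshold_min_cross_entropy(img, 1.0) == pytest.approx(li_oracle(vals))

    def test_correction_factor_is_exact_multiplier(self):
        rng = np.random.default_rng(12)
        img = IntensityImage(rng.integers(1, 40, (8, 8)).astype(float))
        base = threshold_min_cross_entropy(img, 1.0)
        assert threshold_min_cross_entropy(img, 2.0) == 2.0 * base

    def test_li_constant_image_rejected(self):
        with pytest.raises(ValueError):
            threshold_min_cross_entropy(IntensityImage(np.full((3, 3), 2.0)), 1.0)

    def test_threshold_spec_manual_requires_value(self):
        with pytest.raises(ValueError):
            ThresholdSpec(method="manual")
        with pytest.raises(ValueError):
            ThresholdSpec(method="otsu", manual_value=3.0)


# ---------------------------------------------------------------------------
# Seeded propagation and its Dijkstra oracle
# ---------------------------------------------------------------------------

def dijkstra_oracle(nuclei, guide, foreground, lam):
    """Independent geodesic assignment via scipy's sparse-graph Dijkstra."""
    h, w = nuclei.shape
    fg = foreground | (nuclei > 0)
    idx = np.arange(h * w).reshape(h, w)
    rows, cols, costs = [], [], []
    intens = guide.astype(float)
    for (di, dj) in ((0, 1), (1, 0)):
        a = idx[: h - di, : w - dj].ravel()
        b = idx[di:, dj:].ravel()
        ok = fg.ravel()[a] & fg.ravel()[b]
        c = np.sqrt(lam**2 + (intens.ravel()[a] - intens.ravel()[b]) ** 2)
        rows += [a[ok], b[ok]]
        cols += [b[ok], a[ok]]
        costs += [c[ok], c[ok]]
    g = coo_matrix(
        (np.concatenate(costs), (np.concatenate(rows), np.concatenate(cols))),
        shape=(h * w, h * w),
    ).tocsr()
    labels = np.unique(nuclei[nuclei > 0])
    dists = np.vstack(
        [
            csgraph_dijkstra(g, indices=np.flatnonzero(nuclei.ravel() == k), min_only=True)
            for k in labels
        ]
    )
    best = np.argmin(dists, axis=0)  # first minimum -> lowest label wins ties
    out = np.where(np.isfinite(dists.min(axis=0)) & fg.ravel(), labels[best], 0)
    out[nuclei.ravel() > 0] = nuclei.ravel()[nuclei.ravel() > 0]
    return out.reshape(h, w)


class TestPropagation:
    def test_single_seed_claims_connected_component(self):
        nuclei = np.zeros((8, 8), dtype=int)
        nuclei[2, 2] = 1
        fg = np.zeros((8, 8), dtype=bool)
        fg[1:5, 1:5] = True
        out = propagate_cells(LabelImage(nuclei), IntensityImage(np.ones((8, 8))), fg)
        assert np.array_equal(out.labels == 1, fg)

    def test_symmetric_seeds_split_at_midline_with_tie_to_lower_label(self):
        nuclei = np.zeros((5, 9), dtype=int)
        nuclei[2, 1], nuclei[2, 7] = 1, 2
        fg = np.ones((5, 9), dtype=bool)
        out = propagate_cells(LabelImage(nuclei), IntensityImage(np.ones((5, 9))), fg).labels
        assert np.all(out[:, :4] == 1)
        assert np.all(out[:, 5:] == 2)
        assert np.all(out[:, 4] == 1)  # equidistant column goes to the lower label

    def test_matches_dijkstra_oracle_on_random_scenes(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            guide = rng.uniform(0, 1, (16, 16))
            fg = rng.uniform(size=(16, 16)) < 0.8
            nuclei = np.zeros((16, 16), dtype=int)
            for k in (1, 2, 3):
                i, j = rng.integers(0, 16, 2)
                nuclei[i, j] = k
                fg[i, j] = True
            got = propagate_cells(
                LabelImage(nuclei), IntensityImage(guide), fg, regularization=0.05
            ).labels
            want = dijkstra_oracle(nuclei, guide, fg, 0.05)
            np.testing.assert_array_equal(got, want)

    def test_output_partitions_reachable_foreground(self):
        rng = np.random.default_rng(14)
        guide = rng.uniform(0, 1, (16, 16))
        nuclei = np.zeros((16, 16), dtype=int)
        nuclei[4, 4], nuclei[11, 11] = 1, 2
        fg = np.ones((16, 16), dtype=bool)
        for lam in (0.0, 0.05, 1.0):
            out = propagate_cells(LabelImage(nuclei), IntensityImage(guide), fg, lam).labels
            assert np.all(out[fg] > 0)
            assert out[4, 4] == 1 and out[11, 11] == 2  # seeds never detach

    def test_empty_seed_image_rejected(self):
        with pytest.raises(ValueError):
            propagate_cells(LabelImage(np.zeros((4, 4), dtype=int)), IntensityImage(np.ones((4, 4))))


# ---------------------------------------------------------------------------
# Compartment derivation and measurement
# ---------------------------------------------------------------------------

class TestCompartments:
    def test_cytoplasm_ring(self):
        cells = np.zeros((7, 7), dtype=int)
        cells[1:6, 1:6] = 4
        nuclei = np.zeros((7, 7), dtype=int)
        nuclei[2:5, 2:5] = 4
        cyt = derive_cytoplasm(LabelImage(cells), LabelImage(nuclei)).labels
        assert (cyt == 4).sum() == 16
        assert np.all(cyt[2:5, 2:5] == 0)

    def test_nuclei_equal_cells_gives_empty_cytoplasm(self):
        lab = LabelImage(np.array([[1, 1], [0, 2]]))
        assert derive_cytoplasm(lab, lab).ids().size == 0

    def test_disjoint_nucleus_id_rejected(self):
        cells = LabelImage(np.array([[1, 1], [0, 0]]))
        nuclei = LabelImage(np.array([[0, 0], [0, 9]]))
        with pytest.raises(ValueError):
            derive_cytoplasm(cells, nuclei)

    def test_mito_mask_full_and_empty(self):
        cyt = LabelImage(np.array([[1, 1], [2, 2]]))
        spec = ThresholdSpec(method="manual", manual_value=5.0)
        hi = IntensityImage(np.full((2, 2), 9.0))
        mito, empty = mask_mitochondria(cyt, hi, spec)
        assert np.array_equal(mito.labels, cyt.labels) and empty == []
        lo = IntensityImage(np.full((2, 2), 1.0))
        mito, empty = mask_mitochondria(cyt, lo, spec)
        assert mito.ids().size == 0 and empty == [1, 2]

    def test_mito_mask_equals_puncta_intersection(self):
        # bright punctum inside the cytoplasm of cell 1, dim background
        cyt = np.zeros((6, 6), dtype=int)
        cyt[1:5, 1:5] = 1
        tmre = np.full((6, 6), 2.0)
        tmre[2:4, 2:4] = 50.0
        tmre[0, 0] = 50.0  # bright pixel outside any cell stays excluded
        mito, empty = mask_mitochondria(
            LabelImage(cyt),
            IntensityImage(tmre),
            ThresholdSpec(method="manual", manual_value=10.0),
        )
        expected = np.zeros((6, 6), dtype=int)
        expected[2:4, 2:4] = 1
        assert np.array_equal(mito.labels, expected)
        assert empty == []

    def test_scene_mito_mask_is_pure_puncta(self, small_scene, small_segmentation):
        seg, _ = small_segmentation
        truth = small_scene.mitochondria.labels
        got = seg.mitochondria.labels
        nz = got > 0
        # every recovered mitochondrial pixel carries its cell's id and
        # (almost) all of them are ground-truth puncta pixels
        assert np.array_equal(got[nz], seg.cytoplasm.labels[nz])
        precision = np.count_nonzero(truth[nz] > 0) / np.count_nonzero(nz)
        assert precision > 0.95

    def test_measure_simple_object(self):
        lab = LabelImage(np.array([[3, 3], [3, 3]]))
        img = IntensityImage(np.array([[1.0, 2.0], [3.0, 4.0]]))
        row = measure_compartments(lab, img).iloc[0]
        assert row.n_pixels == 4 and row["mean"] == 2.5 and row.integrated == 10

    def test_measure_matches_accumulation_oracle(self):
        rng = np.random.default_rng(15)
        lab = LabelImage(rng.integers(0, 4, (12, 12)))
        img = IntensityImage(rng.uniform(0, 5, (12, 12)))
        table = measure_compartments(lab, img).set_index("object_id")
        for k in lab.ids():
            mask = lab.labels == k
            assert table.loc[k, "integrated"] == pytest.approx(img.pixels[mask].sum())
            assert table.loc[k, "mean"] == pytest.approx(img.pixels[mask].mean())

    def test_empty_label_set_gives_empty_table(self):
        table = measure_compartments(LabelImage(np.zeros((3, 3), dtype=int)), IntensityImage(np.ones((3, 3))))
        assert table.empty


class TestSegmentationInvariants:
    def test_pipeline_output_satisfies_all_relations(self, small_segmentation):
        seg, _ = small_segmentation
        seg.validate()

    def test_ground_truth_masks_satisfy_relations(self, small_scene):
        SegmentationResult(
            nuclei=small_scene.nuclei,
            cells=small_scene.cells,
            cytoplasm=small_scene.cytoplasm,
            mitochondria=small_scene.mitochondria,
        ).validate()

    def test_validate_rejects_broken_containment(self):
        nuclei = LabelImage(np.array([[1, 0], [0, 0]]))
        cells = LabelImage(np.array([[2, 2], [0, 0]]))
        bad = SegmentationResult(nuclei, cells, cells, LabelImage(np.zeros((2, 2), dtype=int)))
        with pytest.raises(AssertionError):
            bad.validate()
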