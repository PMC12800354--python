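"""Tissue detection, tessellation and ROI filters against independent oracles."""

import numpy as np
import pytest
from skimage.filters import threshold_otsu as skimage_otsu

from histotx.preproc import (
    DegenerateHistogramError,
    PreprocError,
    apply_learned_filter,
    apply_mask_filter,
    otsu_threshold,
    tessellate,
    tissue_mask,
    train_tile_filter,
)


def brute_force_otsu(hist: np.ndarray) -> int:
    """Exhaustive between-class variance search (the independent oracle)."""
    p = hist / hist.sum()
    levels = np.arange(256)
    best_t, best_v = None, -1.0
    for t in range(1, 256):
        w0, w1 = p[:t].sum(), p[t:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (p[:t] * levels[:t]).sum() / w0
        mu1 = (p[t:] * levels[t:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-9 * max(best_v, 1.0):
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_two_delta_histogram_lowest_tie(self):
        hist = np.zeros(256)
        hist[10], hist[200] = 50, 50
        assert otsu_threshold(hist) == 11

    def test_matches_brute_force_on_random_histograms(self, rng):
        for _ in range(200):
            hist = np.zeros(256)
            occupied = rng.choice(256, size=16, replace=False)
            hist[occupied] = rng.integers(1, 100, size=16)
            assert otsu_threshold(hist) == brute_force_otsu(hist)

    def test_single_level_errors(self):
        hist = np.zeros(256)
        hist[42] = 100
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(hist)

    def test_agrees_with_skimage_split(self, rng):
        # same dark/bright partition as skimage on well-separated data
        vals = np.concatenate(
            [rng.normal(60, 10, 5000), rng.normal(200, 10, 5000)]
        ).clip(0, 255)
        hist = np.bincount(vals.astype(np.uint8), minlength=256)
        ours = otsu_threshold(hist)
        theirs = skimage_otsu(hist=(hist, np.arange(256)))
        assert (np.arange(256) < ours).sum() == pytest.approx(
            (np.arange(256) <= theirs).sum(), abs=2
        )


class TestTissueMask:
    def test_uniform_image_errors(self):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        with pytest.raises(DegenerateHistogramError):
            tissue_mask(img)

    def test_dark_blobs_on_white_recovered(self, rng):
        img = np.full((128, 128, 3), 250, dtype=np.uint8)
        painted = np.zeros((128, 128), dtype=bool)
        painted[20:60, 30:90] = True
        img[painted] = rng.integers(80, 140, (painted.sum(), 3))
        tm = tissue_mask(img)
        assert tm.mask[painted].mean() >= 0.99
        assert tm.mask[~painted].mean() <= 0.01

    def test_two_level_inversion_flips_mask(self):
        img = np.full((32, 32, 3), 200, dtype=np.uint8)
        img[:16] = 40
        tm = tissue_mask(img)
        inv = tissue_mask(255 - img)
        assert np.array_equal(tm.mask, ~inv.mask)


class TestTessellate:
    def test_four_patch_grid(self):
        grid = tessellate(np.ones((448, 448), dtype=bool), 224, 0.5)
        assert sorted(map(tuple, grid.coords)) == [
            (0, 0), (0, 224), (224, 0), (224, 224),
        ]
        assert grid.keep["none"].all()

    def test_partial_column_discarded(self):
        grid = tessellate(np.ones((224, 230), dtype=bool), 224, 0.5)
        assert len(grid.coords) == 1 and tuple(grid.coords[0]) == (0, 0)

    def test_patch_larger_than_image_errors(self):
        with pytest.raises(PreprocError):
            tessellate(np.ones((100, 100), dtype=bool), 224, 0.5)

    def test_random_blob_mask_matches_pixel_count_oracle(self, rng):
        mask = rng.random((300, 260)) < 0.4
        ps, minf = 64, 0.35
        grid = tessellate(mask, ps, minf)
        expected = []
        for y in range(0, 300 - ps + 1, ps):
            for x in range(0, 260 - ps + 1, ps):
                expected.append(mask[y : y + ps, x : x + ps].sum() >= minf * ps * ps)
        assert np.array_equal(grid.keep["none"], np.array(expected))

    def test_grid_is_regular_and_non_overlapping(self, rng):
        grid = tessellate(rng.random((500, 450)) < 0.5, 100, 0.0)
        assert np.all(grid.coords % 100 == 0)
        assert len({tuple(c) for c in grid.coords}) == len(grid.coords)
        assert np.all(grid.coords[:, 0] + 100 <= 450)
        assert np.all(grid.coords[:, 1] + 100 <= 500)


class TestMaskFilter:
    def _grid(self, shape=(256, 256)):
        return tessellate(np.ones(shape, dtype=bool), 64, 0.5)

    def test_all_ones_keeps_tissue_patches(self):
        grid = self._grid()
        apply_mask_filter(grid, np.ones((256, 256), dtype=bool), 0.5)
        assert np.array_equal(grid.keep["mask"], grid.keep["none"])

    def test_all_zeros_keeps_none(self):
        grid = self._grid()
        apply_mask_filter(grid, np.zeros((256, 256), dtype=bool), 0.5)
        assert not grid.keep["mask"].any()

    def test_random_mask_matches_fraction_oracle(self, rng):
        grid = self._grid()
        tumour = rng.random((256, 256)) < 0.5
        apply_mask_filter(grid, tumour, 0.5)
        for i, (x, y) in enumerate(grid.coords):
            frac = tumour[y : y + 64, x : x + 64].mean()
            assert grid.keep["mask"][i] == (
                grid.keep["none"][i] and frac >= 0.5
            )

    def test_shape_mismatch_errors(self):
        grid = self._grid()
        with pytest.raises(PreprocError):
            apply_mask_filter(grid, np.ones((100, 100), dtype=bool))

    def test_filters_are_subsets_of_tissue(self, rng):
        grid = tessellate(rng.random((256, 256)) < 0.6, 64, 0.5)
        apply_mask_filter(grid, rng.random((256, 256)) < 0.3, 0.25)
        assert not (grid.keep["mask"] & ~grid.keep["none"]).any()


class TestTileFilter:
    def test_separable_features_high_heldout_accuracy(self, rng):
        X = np.concatenate(
            [rng.normal(-2, 1, (600, 8)), rng.normal(2, 1, (600, 8))]
        )
        y = np.repeat([0, 1], 600)
        model = train_tile_filter(X[:1000], y[:1000], training_size=3000, seed=0)
        acc = ((model.predict_proba(X[1000:]) >= 0.5).astype(int) == y[1000:]).mean()
        assert acc >= 0.95

    def test_shuffled_labels_chance_accuracy(self, rng):
        X = rng.normal(0, 1, (1000, 8))
        y = rng.integers(0, 2, 1000)
        model = train_tile_filter(X[:800], y[:800], seed=0)
        acc = ((model.predict_proba(X[800:]) >= 0.5).astype(int) == y[800:]).mean()
        assert 0.35 < acc < 0.65

    def test_default_training_size_is_3000(self, rng):
        X = np.concatenate([rng.normal(-1, 1, (2500, 4)), rng.normal(1, 1, (2500, 4))])
        y = np.repeat([0, 1], 2500)
        model = train_tile_filter(X, y, seed=0)
        assert model.training_size == 3000

    def test_single_class_errors(self, rng):
        with pytest.raises(PreprocError):
            train_tile_filter(rng.normal(0, 1, (50, 4)), np.zeros(50))


class TestLearnedFilter:
    def test_threshold_zero_equals_no_filter(self, rng):
        grid = tessellate(np.ones((256, 256), dtype=bool), 64, 0.5)
        n = grid.n_kept("none")
        model = train_tile_filter(
            np.concatenate([rng.normal(-2, 1, (100, 4)), rng.normal(2, 1, (100, 4))]),
            np.repeat([0, 1], 100),
            seed=0,
        )
        model.threshold = 1e-12
        apply_learned_filter(grid, model, rng.normal(0, 1, (n, 4)))
        assert np.array_equal(grid.keep["learned"], grid.keep["none"])

    def test_misaligned_features_error(self, rng):
        grid = tessellate(np.ones((256, 256), dtype=bool), 64, 0.5)
        model = train_tile_filter(
            np.concatenate([rng.normal(-2, 1, (100, 4)), rng.normal(2, 1, (100, 4))]),
            np.repeat([0, 1], 100),
            seed=0,
        )
        with pytest.raises(PreprocError):
            apply_learned_filter(grid, model, rng.normal(0, 1, (3, 4)))

    def test_infinite_margin_model_equals_oracle_filter(self, rng):
        # a filter scoring exactly the tumour indicator reproduces the mask rule
        grid = tessellate(np.ones((256, 256), dtype=bool), 64, 0.5)
        tumour = np.zeros((256, 256), dtype=bool)
        tumour[:128] = True
        apply_mask_filter(grid, tumour, 0.5)
        from histotx.preproc import TileFilterModel

        frac = np.array(
            [tumour[y : y + 64, x : x + 64].mean() for x, y in grid.coords]
        )
        feats = (frac[grid.keep["none"]] >= 0.5).astype(float)[:, None]
        model = TileFilterModel(weights=np.array([1000.0]), bias=-500.0)
        apply_learned_filter(grid, model, feats)
        assert np.array_equal(grid.keep["learned"], grid.keep["mask"])
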