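"""Synthetic smear generator: masks, determinism, stitching, datasets."""

import numpy as np
import pytest
from scipy import stats
from skimage.measure import label as cc_label
from skimage.transform import resize

from leukoseg import io
from leukoseg.synthdata import (DEFAULT_PALETTE, SyntheticSmearSpec,
                                generate_smear, make_easy_task, sample_classes,
                                stitch_tiles, write_dataset)


class TestGenerateSmear:
    def test_empty_scene_has_zero_mask(self):
        spec = SyntheticSmearSpec(canvas_size=(64, 64), n_cells=0, seed=3)
        img, mask = generate_smear(spec)
        assert img.shape == (64, 64, 3) and img.dtype == np.uint8
        assert mask.max() == 0

    def test_requested_classes_present_with_positive_counts(self):
        spec = SyntheticSmearSpec(canvas_size=(256, 256), n_cells=4, seed=21)
        _, mask = generate_smear(spec)
        present = set(np.unique(mask)) - {0}
        rng = np.random.default_rng(21)
        assert len(present) >= 1
        for cls in present:
            assert (mask == cls).sum() > 50

    def test_seed_determinism_and_distinctness(self):
        spec = SyntheticSmearSpec(canvas_size=(96, 96), n_cells=1, seed=9)
        a_img, a_mask = generate_smear(spec)
        b_img, b_mask = generate_smear(spec)
        np.testing.assert_array_equal(a_img, b_img)
        np.testing.assert_array_equal(a_mask, b_mask)
        c_img, _ = generate_smear(SyntheticSmearSpec(canvas_size=(96, 96),
                                                     n_cells=1, seed=10))
        assert not np.array_equal(a_img, c_img)

    @pytest.mark.parametrize("cls", [1, 4, 5])
    def test_cell_region_is_connected(self, cls):
        mix = tuple(1.0 if i == cls - 1 else 0.0 for i in range(5))
        spec = SyntheticSmearSpec(canvas_size=(160, 160), n_cells=1,
                                  class_mix=mix, rbc_density=0.0, seed=4)
        _, mask = generate_smear(spec)
        assert cc_label(mask == cls).max() == 1

    def test_overcrowded_scene_raises(self):
        spec = SyntheticSmearSpec(canvas_size=(96, 96), n_cells=30, seed=0)
        with pytest.raises(RuntimeError, match="fewer cells"):
            generate_smear(spec)

    def test_class_mix_chi_square(self):
        mix = (0.1, 0.2, 0.3, 0.25, 0.15)
        draws = sample_classes(1000, mix, np.random.default_rng(42))
        observed = np.bincount(draws, minlength=6)[1:]
        _, p = stats.chisquare(observed, 1000 * np.asarray(mix))
        assert p > 0.01


class TestStitchTiles:
    def _tiles(self, n, seed=0, size=(96, 96)):
        # non-granular classes only, so each cell is one connected region
        mix = (0.34, 0.0, 0.0, 0.33, 0.33)
        return [generate_smear(SyntheticSmearSpec(canvas_size=size, n_cells=1,
                                                  rbc_density=0.0, class_mix=mix,
                                                  seed=seed + i))
                for i in range(n)]

    def test_grid2_contains_four_cells(self):
        img, mask = stitch_tiles(self._tiles(4), 2)
        assert img.shape == (512, 512, 3) and mask.shape == (512, 512)
        n_regions = cc_label(mask > 0).max()
        assert n_regions == 4

    def test_grid4_tile_regions_are_128(self):
        tiles = self._tiles(16)
        img, mask = stitch_tiles(tiles, 4)
        assert cc_label(mask > 0).max() == 16
        # block structure: tile (0,0) occupies exactly a 128x128 cell
        rimg = resize(np.asarray(tiles[0][0], float), (128, 128, 3), order=1,
                      preserve_range=True, anti_aliasing=True)
        np.testing.assert_array_equal(
            img[:128, :128], np.clip(np.rint(rimg), 0, 255).astype(np.uint8))

    def test_wrong_tile_count_rejected(self):
        with pytest.raises(ValueError):
            stitch_tiles(self._tiles(3), 2)
        with pytest.raises(ValueError):
            stitch_tiles(self._tiles(4), 5)


class TestWriteDataset:
    def test_round_trip_and_manifest(self, tmp_path):
        specs = [SyntheticSmearSpec(canvas_size=(96, 96), n_cells=1, seed=i)
                 for i in range(6)]
        manifest = write_dataset(specs, tmp_path)
        assert manifest["n_pairs"] == 6
        assert len(manifest["pairs"]) == 6
        for i, entry in enumerate(manifest["pairs"]):
            _, mask = generate_smear(specs[i])
            stored = io.read_mask(tmp_path / entry["mask"])
            np.testing.assert_array_equal(stored, mask)
            labels, counts = np.unique(mask, return_counts=True)
            assert entry["class_counts"] == {int(l): int(c)
                                             for l, c in zip(labels, counts)}


class TestEasyTask:
    def test_pairs_shape_labels_and_determinism(self):
        pairs = make_easy_task(4, size=32, seed=5)
        assert len(pairs) == 4
        for img, mask in pairs:
            assert img.shape == (32, 32, 3) and mask.shape == (32, 32)
            assert mask.min() >= 0 and mask.max() <= 3
        again = make_easy_task(4, size=32, seed=5)
        for (a, am), (b, bm) in zip(pairs, again):
            np.testing.assert_array_equal(a, b)
            np.testing.assert_array_equal(am, bm)
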