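"""Connected domains, closing, area filtering and gland counting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from glandseg import (
    FilterConfig,
    SceneConfig,
    count_glands,
    filter_regions,
    generate_scene,
    label_components,
    morphological_close,
)


def flood_fill_labels(mask, connectivity=8):
    """Independent BFS labelling oracle."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    labels = np.zeros((h, w), dtype=int)
    k = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not labels[r, c]:
                k += 1
                stack = [(r, c)]
                labels[r, c] = k
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] \
                                and not labels[nr, nc]:
                            labels[nr, nc] = k
                            stack.append((nr, nc))
    return labels, k


class TestLabelComponents:
    def test_empty_mask(self):
        assert label_components(np.zeros((5, 5), np.uint8)).n_regions == 0

    def test_diagonal_adjacency_convention(self):
        mask = np.zeros((4, 4), np.uint8)
        mask[1, 1] = mask[2, 2] = 1
        assert label_components(mask, connectivity=8).n_regions == 1
        assert label_components(mask, connectivity=4).n_regions == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(10):
            mask = (rng.random((40, 40)) > 0.75).astype(np.uint8)
            regions = label_components(mask, connectivity)
            oracle_labels, oracle_k = flood_fill_labels(mask, connectivity)
            assert regions.n_regions == oracle_k
            # identical partition up to label permutation
            pairs = {(int(a), int(b)) for a, b in
                     zip(regions.labels.ravel(), oracle_labels.ravel())}
            assert len(pairs) == oracle_k + (mask == 0).any()

    def test_region_properties_consistent(self, small_scene):
        regions = label_components(small_scene.mask)
        assert regions.areas.sum() == small_scene.mask.sum()
        frame = regions.to_frame()
        assert len(frame) == regions.n_regions
        assert (frame["area"] >= 1).all()

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            label_components(np.array([[0, 2], [1, 0]]))


class TestClosing:
    def test_radius_zero_is_identity(self, small_scene):
        assert np.array_equal(morphological_close(small_scene.mask, 0),
                              small_scene.mask)

    def test_extensive_and_idempotent(self, rng):
        mask = (rng.random((30, 30)) > 0.8).astype(np.uint8)
        closed = morphological_close(mask, 1)
        assert (closed >= mask).all()
        assert np.array_equal(morphological_close(closed, 1), closed)

    def test_nearby_spots_merge_into_one_component(self):
        """Two glands 1 px apart weld together under closing — the known
        adhesion failure mode that biases counts low."""
        mask = np.zeros((9, 13), np.uint8)
        mask[3:6, 2:5] = 1
        mask[3:6, 6:9] = 1   # gap of one column
        assert label_components(mask).n_regions == 2
        closed = morphological_close(mask, 1)
        assert label_components(closed).n_regions == 1


class TestFilterAndCount:
    def test_area_window_filtering(self):
        mask = np.zeros((6, 16), np.uint8)
        mask[1, 1] = 1                 # area 1
        mask[3, 3:6] = 1               # area 3
        mask[1:2, 8:13] = 1            # area 5
        regions = filter_regions(label_components(mask),
                                 FilterConfig(min_area=2))
        assert sorted(regions.areas.tolist()) == [3, 5]
        assert set(np.unique(regions.labels)) == {0, 1, 2}

    def test_min_area_one_is_identity(self, small_scene):
        regions = label_components(small_scene.mask)
        kept = filter_regions(regions, FilterConfig(min_area=1))
        assert kept.n_regions == regions.n_regions

    def test_all_specks_removed(self):
        mask = np.eye(7, dtype=np.uint8)[::2]  # isolated single pixels
        regions = filter_regions(label_components(mask, connectivity=4),
                                 FilterConfig(min_area=2, connectivity=4))
        assert regions.n_regions == 0

    def test_count_on_perfect_mask_recovers_true_count(self):
        scene = generate_scene(SceneConfig(width=250, height=200, spot_count=40,
                                           spot_radius_range=(1, 3), seed=11))
        cfg = FilterConfig(min_area=2, closing_radius=0)
        assert count_glands(scene.mask, cfg) == 40

    def test_specks_do_not_inflate_count(self, rng):
        scene = generate_scene(SceneConfig(width=200, height=150, spot_count=10,
                                           spot_radius_range=(2, 3), seed=5))
        mask = scene.mask.copy()
        specks = 0
        while specks < 7:
            r, c = rng.integers(0, 150), rng.integers(0, 200)
            # a speck must not touch an existing region (8-adjacency)
            if mask[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2].sum() == 0:
                mask[r, c] = 1
                specks += 1
        cfg = FilterConfig(min_area=2, closing_radius=0)
        assert count_glands(mask, cfg) == 10

    def test_empty_mask_counts_zero(self):
        assert count_glands(np.zeros((20, 20), np.uint8)) == 0

    def test_count_invariant_under_flips(self, small_scene):
        cfg = FilterConfig(min_area=2, closing_radius=0)
        base = count_glands(small_scene.mask, cfg)
        for variant in (small_scene.mask[::-1], small_scene.mask[:, ::-1],
                        small_scene.mask[::-1, ::-1], small_scene.mask.T):
            assert count_glands(np.ascontiguousarray(variant), cfg) == base

    @given(st.integers(1, 8))
    def test_raising_min_area_never_increases_count(self, min_area):
        mask = (np.random.default_rng(99).random((50, 50)) > 0.8).astype(np.uint8)
        counts = [count_glands(mask, FilterConfig(min_area=m))
                  for m in range(1, min_area + 1)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(min_area=0)
        with pytest.raises(ValueError):
            FilterConfig(min_area=5, max_area=4)
        with pytest.raises(ValueError):
            FilterConfig(connectivity=6)
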