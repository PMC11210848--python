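import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nbacklight import (
    AtlasLabels,
    VoxelGrid,
    cluster_median_bold,
    clusters_to_table,
    extract_clusters,
    label_clusters,
    select_clusters,
)
from nbacklight.bold_extraction import TrialPatternSet
from nbacklight.cluster_report import cluster_mask_volume
from nbacklight.searchlight import AccuracyMap

from _oracles import flood_fill_components

GRID = VoxelGrid((12, 12, 12))


def acc_map(values, mask=None, grid=GRID):
    mask = np.ones(grid.shape, bool) if mask is None else mask
    vals = np.where(mask, values, np.nan)
    return AccuracyMap(grid=grid, values=vals, mask=mask, group="control", meta={})


def blob_map(blob_voxels, blob_value=0.8, background=0.5):
    values = np.full(GRID.shape, background)
    for v in blob_voxels:
        values[v] = blob_value
    return acc_map(values)


def cube(corner, side):
    return [
        (corner[0] + i, corner[1] + j, corner[2] + k)
        for i in range(side)
        for j in range(side)
        for k in range(side)
    ]


class TestExtractClusters:
    def test_single_blob_counted_by_hand(self):
        # 25 suprathreshold voxels: a 3x3x3 cube missing two corners
        blob = cube((2, 2, 2), 3)[:-2]
        clusters = extract_clusters(blob_map(blob), acc_threshold=0.65, min_voxels=20)
        assert len(clusters) == 1
        assert clusters[0].size == 25
        assert clusters[0].peak_accuracy == pytest.approx(0.8)
        assert clusters[0].volume_mm3 == pytest.approx(25 * 27.0)

    def test_small_blob_dropped(self):
        blob = cube((2, 2, 2), 2) + [(4, 2, 2), (4, 3, 2)]  # 10 voxels
        assert extract_clusters(blob_map(blob)) == []

    def test_uniform_chance_map_yields_nothing(self):
        assert extract_clusters(acc_map(np.full(GRID.shape, 0.5))) == []

    def test_threshold_is_strict(self):
        blob = cube((2, 2, 2), 3)
        clusters = extract_clusters(blob_map(blob, blob_value=0.65), min_voxels=1)
        assert clusters == []

    def test_connectivity_modes_differ_on_diagonal_touch(self):
        values = np.full(GRID.shape, 0.5)
        for v in cube((1, 1, 1), 2) + cube((3, 3, 3), 2):  # touch only at a vertex
            values[v] = 0.9
        m = acc_map(values)
        assert len(extract_clusters(m, min_voxels=1, connectivity=26)) == 1
        assert len(extract_clusters(m, min_voxels=1, connectivity=6)) == 2

    def test_sorted_by_peak_accuracy_with_sequential_ids(self):
        values = np.full(GRID.shape, 0.5)
        for v in cube((1, 1, 1), 2):
            values[v] = 0.7
        for v in cube((8, 8, 8), 2):
            values[v] = 0.9
        clusters = extract_clusters(acc_map(values), min_voxels=1)
        assert [c.cluster_id for c in clusters] == [1, 2]
        assert clusters[0].peak_accuracy > clusters[1].peak_accuracy

    @given(st.integers(0, 10_000), st.sampled_from([6, 26]))
    def test_components_match_flood_fill_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        shape = (6, 6, 6)
        mask = rng.random(shape) < 0.4
        values = np.where(mask, 0.9, 0.1)
        m = acc_map(values, grid=VoxelGrid(shape))
        clusters = extract_clusters(m, min_voxels=1, connectivity=connectivity)
        ours = {frozenset(map(tuple, c.voxels)) for c in clusters}
        assert ours == flood_fill_components(mask, connectivity)

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        values = 0.4 + 0.6 * rng.random(GRID.shape)
        m = acc_map(values)
        prev = None
        for thr in (0.5, 0.6, 0.7, 0.8):
            ids = {frozenset(map(tuple, c.voxels)) for c in extract_clusters(m, acc_threshold=thr, min_voxels=2)}
            if prev is not None:
                # every cluster at the higher threshold is inside one at the lower
                for comp in ids:
                    assert any(comp <= old for old in prev)
            prev = ids


class TestSelectClusters:
    def test_volume_and_peak_rule(self):
        # 20 voxels at 3 mm = 540 mm^3 >= 520 retained at peak .72;
        # 18 voxels = 486 mm^3 dropped despite peak .9
        values = np.full(GRID.shape, 0.5)
        for v in cube((1, 1, 1), 3)[:20]:
            values[v] = 0.72
        for v in cube((7, 7, 7), 3)[:18]:
            values[v] = 0.9
        clusters = extract_clusters(acc_map(values), min_voxels=1)
        kept = select_clusters(clusters)
        assert len(kept) == 1
        assert kept[0].size == 20

    def test_empty_input_empty_output(self):
        assert select_clusters([]) == []

    def test_selection_preserves_order_and_is_monotone(self):
        rng = np.random.default_rng(6)
        values = 0.4 + 0.6 * rng.random(GRID.shape)
        clusters = extract_clusters(acc_map(values), acc_threshold=0.5, min_voxels=2)
        kept = select_clusters(clusters, min_volume_mm3=100, min_peak_accuracy=0.8)
        assert [c.cluster_id for c in kept] == sorted(c.cluster_id for c in kept)
        stricter = select_clusters(clusters, min_volume_mm3=200, min_peak_accuracy=0.9)
        assert {c.cluster_id for c in stricter} <= {c.cluster_id for c in kept}


class TestLabelClusters:
    def make_cluster(self, voxels):
        values = np.full(GRID.shape, 0.5)
        for v in voxels:
            values[v] = 0.9
        return extract_clusters(acc_map(values), min_voxels=1)

    def test_single_region_full_coverage(self):
        atlas = AtlasLabels(data=np.full(GRID.shape, 3, int), names={3: "right angular gyrus"})
        (cluster,) = label_clusters(self.make_cluster(cube((2, 2, 2), 2)), atlas)
        assert cluster.atlas_coverage == [("right angular gyrus", pytest.approx(100.0))]

    def test_straddling_regions_counted(self):
        data = np.zeros(GRID.shape, int)
        data[:4] = 1
        data[4:] = 2
        atlas = AtlasLabels(data=data, names={1: "A", 2: "B"})
        voxels = [(3, 2, 2 + i) for i in range(5)] + [(4, 2, 2 + i) for i in range(5)] + [
            (3, 3, 2 + i) for i in range(5)
        ] + [(3, 4, 2 + i) for i in range(5)]
        (cluster,) = label_clusters(self.make_cluster(voxels), atlas)
        assert cluster.atlas_coverage[0] == ("A", pytest.approx(75.0))
        assert cluster.atlas_coverage[1] == ("B", pytest.approx(25.0))

    def test_zero_atlas_is_unlabeled(self):
        atlas = AtlasLabels(data=np.zeros(GRID.shape, int), names={})
        (cluster,) = label_clusters(self.make_cluster(cube((2, 2, 2), 2)), atlas)
        assert cluster.atlas_coverage == [("unlabeled", pytest.approx(100.0))]

    def test_report_table_columns(self):
        atlas = AtlasLabels(data=np.zeros(GRID.shape, int), names={})
        clusters = label_clusters(self.make_cluster(cube((2, 2, 2), 3)), atlas)
        table = clusters_to_table(clusters)
        assert {"cluster_id", "peak_accuracy", "volume_mm3", "top_regions"} <= set(table.columns)
        vol = cluster_mask_volume(clusters, GRID)
        assert (vol == 1).sum() == clusters[0].size


class TestClusterMedians:
    def make_sets(self, values_fn, n_participants=2, n_per_class=2):
        mask = np.ones(GRID.shape, bool)
        sets = []
        for p in range(n_participants):
            rows, labels = [], []
            for tp in ("baseline", "followup"):
                for level in (0, 2):
                    for trial in range(n_per_class):
                        rows.append(values_fn(p, tp, level, trial))
                        labels.append({"time_point": tp, "level": level, "block": 0, "trial": trial})
            sets.append(
                TrialPatternSet(
                    participant=f"p{p}",
                    group="control",
                    data=np.array(rows, dtype=float),
                    labels=pd.DataFrame(labels),
                    mask=mask,
                    grid=GRID,
                    lag_window=(2, 3),
                )
            )
        return sets

    def cluster_of(self, voxels):
        values = np.full(GRID.shape, 0.5)
        for v in voxels:
            values[v] = 0.9
        return extract_clusters(acc_map(values), min_voxels=1)

    def test_constant_values_give_constant_median(self):
        nvox = GRID.n_voxels
        sets = self.make_sets(lambda p, tp, level, trial: np.full(nvox, 4.5))
        table = cluster_median_bold(self.cluster_of(cube((2, 2, 2), 2)), sets).table
        assert np.allclose(table["median_bold"], 4.5)
        # one cell per cluster x participant x time point x level
        assert len(table) == 1 * 2 * 2 * 2

    def test_textbook_median(self):
        voxels = [(2, 2, 2 + i) for i in range(5)]
        cluster = self.cluster_of(voxels)
        flat = np.ravel_multi_index(tuple(np.array(voxels).T), GRID.shape)

        def values(p, tp, level, trial):
            row = np.zeros(GRID.n_voxels)
            row[flat] = [1, 2, 3, 4, 5]
            return row

        sets = self.make_sets(values, n_participants=2, n_per_class=1)
        table = cluster_median_bold(cluster, sets).table
        assert np.allclose(table["median_bold"], 3.0)

    def test_followup_shift_moves_median_with_matching_sign(self):
        nvox = GRID.n_voxels

        def values(p, tp, level, trial):
            base = np.zeros(nvox)
            if tp == "followup" and level == 2:
                base += 2.5
            return base

        sets = self.make_sets(values)
        table = cluster_median_bold(self.cluster_of(cube((3, 3, 3), 2)), sets).table
        fu = table[(table["time_point"] == "followup") & (table["level"] == 2)]["median_bold"]
        base = table[(table["time_point"] == "baseline") & (table["level"] == 2)]["median_bold"]
        assert np.all(fu.to_numpy() - base.to_numpy() == pytest.approx(2.5))

    def test_cluster_outside_mask_raises(self):
        mask = np.ones(GRID.shape, bool)
        mask[2, 2, 2] = False
        sets = self.make_sets(lambda p, tp, level, trial: np.zeros(GRID.n_voxels))
        holed = [
            TrialPatternSet(
                ps.participant,
                ps.group,
                np.zeros((ps.data.shape[0], int(mask.sum()))),
                ps.labels,
                mask,
                GRID,
                ps.lag_window,
            )
            for ps in sets
        ]
        with pytest.raises(ValueError, match="outside the pattern mask"):
            cluster_median_bold(self.cluster_of(cube((2, 2, 2), 2)), holed)
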