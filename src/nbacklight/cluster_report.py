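"""Cluster extraction, atlas labeling and cluster-median BOLD summaries.

Accuracy maps are thresholded (strictly above the 0.65 cut-off), their
suprathreshold voxels grouped into connected components (26-connectivity
by default, as in common neuroimaging cluster reports), and components
below the 20-voxel size floor discarded.  A second, stricter selection
stage keeps clusters with peak accuracy >= 0.7 and volume >= 520 mm^3
for downstream analyses.  Selected clusters can be labeled against any
label volume on the same grid (an AAL-style parcellation supplied by the
user; tests use a synthetic parcellation) and summarised as per
participant / time point / task level medians of 0-back-referenced BOLD
values pooled over member voxels and trials -- one number per cell, so
the group-level tests operate on one value per participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import VoxelGrid
from .searchlight import AccuracyMap

__all__ = [
    "ClusterRecord",
    "AtlasLabels",
    "ClusterMedianTable",
    "extract_clusters",
    "select_clusters",
    "label_clusters",
    "cluster_median_bold",
    "clusters_to_table",
    "cluster_mask_volume",
]


@dataclass(eq=False)
class ClusterRecord:
    """A connected suprathreshold region of an accuracy map."""

    cluster_id: int
    group: str
    voxels: np.ndarray  # (size, 3) voxel indices
    size: int
    volume_mm3: float
    peak_vox: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    peak_accuracy: float
    atlas_coverage: list = field(default_factory=list)  # [(label name, percent)]


@dataclass(eq=False)
class AtlasLabels:
    """An integer label volume plus a label -> region-name table."""

    data: np.ndarray
    names: dict

    @classmethod
    def from_files(cls, label_nifti, names_tsv=None) -> "AtlasLabels":
        img = nib.load(str(label_nifti))
        data = np.asanyarray(img.dataobj).astype(int)
        names: dict[int, str] = {}
        if names_tsv is not None:
            table = pd.read_csv(names_tsv, sep="\t")
            names = dict(zip(table.iloc[:, 0].astype(int), table.iloc[:, 1].astype(str)))
        return cls(data=data, names=names)

    def name_of(self, label: int) -> str:
        if label == 0:
            return "unlabeled"
        return self.names.get(int(label), f"region_{int(label)}")


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def extract_clusters(
    acc: AccuracyMap,
    acc_threshold: float = 0.65,
    min_voxels: int = 20,
    connectivity: int = 26,
) -> list[ClusterRecord]:
    """Connected components of {accuracy > threshold}, size-filtered.

    The threshold comparison is strict (a cut-off), the size floor
    inclusive-by-count (components with fewer than ``min_voxels`` voxels
    are dropped).  Records are sorted by peak accuracy, descending, and
    numbered from 1 in that order.  An empty list is a valid result.
    """
    if not (0.0 < acc_threshold < 1.0):
        raise ValueError("acc_threshold must be in (0, 1)")
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    above = np.zeros(acc.grid.shape, dtype=bool)
    above[acc.mask] = acc.values[acc.mask] > acc_threshold
    labeled, n_comp = ndimage.label(above, structure=_connectivity_structure(connectivity))

    records = []
    for comp in range(1, n_comp + 1):
        voxels = np.argwhere(labeled == comp)
        if voxels.shape[0] < min_voxels:
            continue
        vals = acc.values[tuple(voxels.T)]
        peak_local = int(np.argmax(vals))
        peak_vox = tuple(int(v) for v in voxels[peak_local])
        records.append(
            ClusterRecord(
                cluster_id=0,
                group=acc.group,
                voxels=voxels,
                size=int(voxels.shape[0]),
                volume_mm3=float(voxels.shape[0] * acc.grid.voxel_volume),
                peak_vox=peak_vox,
                peak_mm=tuple(float(x) for x in acc.grid.world_coords(np.array(peak_vox))),
                peak_accuracy=float(vals[peak_local]),
            )
        )
    records.sort(key=lambda r: -r.peak_accuracy)
    for i, record in enumerate(records):
        record.cluster_id = i + 1
    return records


def select_clusters(
    clusters: list[ClusterRecord],
    min_volume_mm3: float = 520.0,
    min_peak_accuracy: float = 0.7,
) -> list[ClusterRecord]:
    """Second-stage selection: volume and peak-accuracy floors, inclusive."""
    if min_volume_mm3 <= 0 or min_peak_accuracy <= 0:
        raise ValueError("selection thresholds must be positive")
    return [
        c
        for c in clusters
        if c.volume_mm3 >= min_volume_mm3 and c.peak_accuracy >= min_peak_accuracy
    ]


def label_clusters(clusters: list[ClusterRecord], atlas: AtlasLabels) -> list[ClusterRecord]:
    """Attach atlas coverage (region name, % of cluster voxels), descending."""
    for cluster in clusters:
        labels = atlas.data[tuple(cluster.voxels.T)]
        uniq, counts = np.unique(labels, return_counts=True)
        order = np.argsort(-counts, kind="stable")
        cluster.atlas_coverage = [
            (atlas.name_of(int(uniq[i])), 100.0 * counts[i] / cluster.size) for i in order
        ]
    return clusters


@dataclass(eq=False)
class ClusterMedianTable:
    """Median 0-back-referenced BOLD per (cluster, participant, time point, level)."""

    table: pd.DataFrame
    aggregation: str = (
        "median over member voxels x trials, pooled within participant/time point/level"
    )


def cluster_median_bold(clusters: list[ClusterRecord], pattern_sets) -> ClusterMedianTable:
    """Summarise trial patterns inside each cluster as one median per cell.

    For every cluster, participant, time point and task level present in
    the pattern sets, the member voxels' values over all of that cell's
    trials are pooled and reduced to their median.  Cluster voxels must
    lie inside the patterns' mask.
    """
    rows = []
    for ps in pattern_sets:
        col_of = np.full(ps.grid.shape, -1, dtype=np.int64)
        col_of[ps.mask] = np.arange(int(ps.mask.sum()))
        for cluster in clusters:
            cols = col_of[tuple(cluster.voxels.T)]
            if np.any(cols < 0):
                raise ValueError(
                    f"cluster {cluster.cluster_id} has voxels outside the pattern mask "
                    f"of participant {ps.participant}"
                )
            for (tp, level), sub in ps.labels.groupby(["time_point", "level"]):
                block = ps.data[np.ix_(sub.index.to_numpy(), cols)]
                rows.append(
                    {
                        "cluster_id": cluster.cluster_id,
                        "participant": ps.participant,
                        "group": ps.group,
                        "time_point": tp,
                        "level": int(level),
                        "median_bold": float(np.median(block)),
                    }
                )
    table = pd.DataFrame(rows)
    if len(table) and not np.all(np.isfinite(table["median_bold"])):
        raise ValueError("non-finite cluster medians")
    return ClusterMedianTable(table=table)


def clusters_to_table(clusters: list[ClusterRecord], top_regions: int = 3) -> pd.DataFrame:
    """Flatten cluster records into a report table (one row per cluster)."""
    rows = []
    for c in clusters:
        cover = "; ".join(f"{name} ({pct:.1f}%)" for name, pct in c.atlas_coverage[:top_regions])
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "group": c.group,
                "peak_x_mm": c.peak_mm[0],
                "peak_y_mm": c.peak_mm[1],
                "peak_z_mm": c.peak_mm[2],
                "peak_accuracy": c.peak_accuracy,
                "size_vox": c.size,
                "volume_mm3": c.volume_mm3,
                "top_regions": cover,
            }
        )
    return pd.DataFrame(rows)


def cluster_mask_volume(clusters: list[ClusterRecord], grid: VoxelGrid) -> np.ndarray:
    """Label volume with each cluster's id at its member voxels."""
    out = np.zeros(grid.shape, dtype=np.int16)
    for c in clusters:
        out[tuple(c.voxels.T)] = c.cluster_id
    return out
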