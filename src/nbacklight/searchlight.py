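"""Whole-brain searchlight k-NN classification of measurement time points.

A sphere of fixed world-space radius (4 mm by default, which on a 3 mm
grid means the centre plus its six face neighbours) is scanned across
every in-mask voxel.  At each centre, the trials of all participants --
restricted to the sphere's voxels -- are classified into baseline vs
follow-up with a k-nearest-neighbour classifier under
leave-one-participant-out cross-validation; the pooled prediction
accuracy over all held-out trials is assigned to the centre voxel.  An
accuracy of 0.5 is chance for the balanced two-class problem, 1.0 is
perfect discrimination of the two time points.

Classification is run separately per group, so the accuracy map of a
group reflects how much that group's multivoxel activity patterns
changed between the two time points.

Implementation notes: per-centre computations are independent, and the
map is identical regardless of the order centres are visited.  The inner
loop batches centres with equal sphere size and computes all pairwise
trial distances as Gram matrices in float32; with continuous-valued
patterns, distance ties are measure-zero, and vote ties cannot occur for
odd ``k`` (the default).  The reference :func:`knn_predict` implements
the full deterministic tie policy (nearest neighbour's label, then the
lower class code) and is the semantic contract the fast path follows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy.spatial.distance import cdist

from .bold_extraction import TrialPatternSet
from .grid import VoxelGrid

__all__ = [
    "SphereIndex",
    "AccuracyMap",
    "build_spheres",
    "knn_predict",
    "searchlight_accuracy",
    "accuracy_to_nifti",
    "accuracy_from_nifti",
]


@dataclass(eq=False)
class SphereIndex:
    """Sphere membership for every in-mask centre voxel.

    ``centers`` holds the flat index (into the mask's voxel list) of
    each centre; ``members[i]`` the member-column indices of centre i,
    truncated at the mask boundary.  Columns refer to the voxel order of
    ``np.flatnonzero(mask)``, the order used by trial pattern matrices.
    """

    grid: VoxelGrid
    mask: np.ndarray
    radius_mm: float
    centers: np.ndarray  # (n_centers,) column index of each centre voxel
    members: list  # list of int arrays, one per centre

    @property
    def n_centers(self) -> int:
        return self.centers.size


def sphere_offsets(voxel_size, radius_mm: float) -> np.ndarray:
    """Integer voxel offsets whose world-space distance is <= radius."""
    vs = np.asarray(voxel_size, dtype=float)
    reach = [int(np.floor(radius_mm / v)) for v in vs]
    offs = []
    for di in range(-reach[0], reach[0] + 1):
        for dj in range(-reach[1], reach[1] + 1):
            for dk in range(-reach[2], reach[2] + 1):
                d = np.sqrt((di * vs[0]) ** 2 + (dj * vs[1]) ** 2 + (dk * vs[2]) ** 2)
                if d <= radius_mm:
                    offs.append((di, dj, dk))
    return np.array(offs, dtype=int)


def build_spheres(grid: VoxelGrid, mask: np.ndarray, radius_mm: float) -> SphereIndex:
    """Index the searchlight spheres for every in-mask voxel.

    Distances are Euclidean in world space (voxel offsets scaled by the
    grid's voxel size).  A radius smaller than the smallest voxel
    dimension leaves each sphere with its centre only, which defeats the
    purpose of a searchlight; a warning is emitted.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape does not match grid")
    if radius_mm < min(grid.voxel_size):
        warnings.warn(
            f"radius {radius_mm} mm is smaller than the smallest voxel dimension "
            f"{min(grid.voxel_size)} mm; spheres contain their centre only",
            stacklevel=2,
        )
    offs = sphere_offsets(grid.voxel_size, radius_mm)

    col_of = np.full(grid.shape, -1, dtype=np.int64)
    n_mask = int(mask.sum())
    col_of[mask] = np.arange(n_mask)

    # member table: one shifted copy of col_of per offset
    centers_ijk = np.argwhere(mask)
    member_table = np.full((n_mask, offs.shape[0]), -1, dtype=np.int64)
    shape = np.asarray(grid.shape)
    for o, off in enumerate(offs):
        pos = centers_ijk + off[None, :]
        ok = np.all((pos >= 0) & (pos < shape[None, :]), axis=1)
        member_table[ok, o] = col_of[pos[ok, 0], pos[ok, 1], pos[ok, 2]]

    members = [row[row >= 0] for row in member_table]
    return SphereIndex(
        grid=grid,
        mask=mask,
        radius_mm=float(radius_mm),
        centers=np.arange(n_mask),
        members=members,
    )


def knn_predict(train_rows, train_labels, test_rows, k: int = 5, metric: str = "euclidean"):
    """k-nearest-neighbour prediction with a deterministic tie policy.

    Majority vote of the ``k`` nearest training rows; distance ties are
    broken by lower training-row index, vote ties by the single nearest
    neighbour's label, and any remaining ambiguity by the lower class
    code.  This is the reference semantics the searchlight follows.
    """
    train_rows = np.atleast_2d(np.asarray(train_rows, dtype=float))
    test_rows = np.atleast_2d(np.asarray(test_rows, dtype=float))
    train_labels = np.asarray(train_labels)
    if train_rows.shape[0] == 0:
        raise ValueError("empty training set")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > train_rows.shape[0]:
        raise ValueError(f"k={k} exceeds the {train_rows.shape[0]} training rows")

    D = cdist(test_rows, train_rows, metric=metric)
    classes = np.unique(train_labels)
    out = np.empty(test_rows.shape[0], dtype=train_labels.dtype)
    idx_order = np.arange(train_rows.shape[0])
    for i in range(test_rows.shape[0]):
        order = np.lexsort((idx_order, D[i]))  # distance, then row index
        top = train_labels[order[:k]]
        counts = {c: int(np.sum(top == c)) for c in classes}
        best = max(counts.values())
        tied = sorted([c for c, n in counts.items() if n == best])
        if len(tied) == 1:
            out[i] = tied[0]
        else:
            nearest = train_labels[order[0]]
            out[i] = nearest if nearest in tied else tied[0]
    return out


@dataclass(eq=False)
class AccuracyMap:
    """Per-voxel cross-validated classification accuracy.

    ``values`` is NaN outside the mask and in [0, 1] inside.  ``meta``
    records the sphere radius, k, fold structure and trial counts.
    """

    grid: VoxelGrid
    values: np.ndarray
    mask: np.ndarray
    group: str
    meta: dict

    def __post_init__(self) -> None:
        inside = self.values[self.mask]
        if inside.size and (np.nanmin(inside) < 0 or np.nanmax(inside) > 1):
            raise ValueError("accuracies out of [0, 1]")


_TP_CODE = {"baseline": 0, "followup": 1}


def _stack_patterns(pattern_sets: list[TrialPatternSet]):
    if len(pattern_sets) < 2:
        raise ValueError("leave-one-participant-out needs at least 2 participants")
    mask = pattern_sets[0].mask
    grid = pattern_sets[0].grid
    for ps in pattern_sets[1:]:
        if ps.grid != grid or not np.array_equal(ps.mask, mask):
            raise ValueError("all pattern sets must share grid and mask")
    X, y, subj = [], [], []
    for s_idx, ps in enumerate(pattern_sets):
        codes = ps.labels["time_point"].map(_TP_CODE)
        if codes.isna().any():
            raise ValueError(f"participant {ps.participant}: unknown time point labels")
        if codes.nunique() < 2:
            raise ValueError(
                f"participant {ps.participant} has trials of only one class; "
                "cannot cross-validate time points"
            )
        X.append(ps.data)
        y.append(codes.to_numpy(dtype=np.int64))
        subj.append(np.full(len(ps.labels), s_idx, dtype=np.int64))
    return np.vstack(X), np.concatenate(y), np.concatenate(subj), mask, grid


def searchlight_accuracy(
    pattern_sets: list[TrialPatternSet],
    spheres: SphereIndex | None = None,
    radius_mm: float = 4.0,
    k: int = 5,
    batch_size: int = 8,
) -> AccuracyMap:
    """Leave-one-participant-out k-NN accuracy at every sphere centre.

    For each centre voxel and each fold, the held-out participant's
    trials are classified against all other participants' trials using
    only the sphere's voxels; the map value is the pooled fraction of
    correct predictions over all folds.
    """
    X, y, subj, mask, grid = _stack_patterns(pattern_sets)
    if spheres is None:
        spheres = build_spheres(grid, mask, radius_mm)
    elif spheres.grid != grid or not np.array_equal(spheres.mask, mask):
        raise ValueError("sphere index was built for a different grid/mask")

    n_trials = X.shape[0]
    min_train = min(n_trials - int(np.sum(subj == s)) for s in np.unique(subj))
    if k < 1 or k > min_train:
        raise ValueError(f"k={k} must be in [1, {min_train}] for this fold structure")

    # Sort trials so class-0 columns are contiguous: for odd k the majority
    # vote among the k nearest neighbours equals comparing the ((k+1)/2)-th
    # smallest distance within each class, which needs only cheap argmin
    # sweeps per class block instead of a top-k partition.
    order = np.argsort(y, kind="stable")
    Xf = np.ascontiguousarray(X[order], dtype=np.float32)
    ys = y[order]
    subj_s = subj[order]
    n0 = int(np.sum(ys == 0))
    # +LARGE on same-participant pairs implements leave-one-participant-out
    penalty = (subj_s[:, None] == subj_s[None, :]).astype(np.float32) * np.float32(3.4e38)

    med = (k + 1) // 2
    row_idx = None
    sizes = np.array([m.size for m in spheres.members])
    acc_cols = np.empty(spheres.n_centers)
    for m in np.unique(sizes):
        centers_m = np.flatnonzero(sizes == m)
        idx = np.stack([spheres.members[r] for r in centers_m])  # (n_centers_m, m)
        for start in range(0, centers_m.size, batch_size):
            sel = centers_m[start : start + batch_size]
            cols = idx[start : start + batch_size]  # (B, m)
            Xb = np.ascontiguousarray(np.moveaxis(Xf[:, cols], 1, 0))  # (B, n, m)
            sq = np.einsum("bim,bim->bi", Xb, Xb)
            G = Xb @ np.swapaxes(Xb, 1, 2)
            # per test row i the ranking over candidates j only needs
            # |x_j|^2 - 2 <x_i, x_j>; the |x_i|^2 term is constant per row
            np.multiply(G, np.float32(-2.0), out=G)
            G += sq[:, None, :]
            G += penalty
            B = G.shape[0]
            flat = G.reshape(B * n_trials, n_trials)
            if row_idx is None or row_idx.size != flat.shape[0]:
                row_idx = np.arange(flat.shape[0])
            if k % 2 == 1:
                kth = np.empty((2, flat.shape[0]), dtype=np.float32)
                for c, block in enumerate((flat[:, :n0], flat[:, n0:])):
                    for _sweep in range(med - 1):
                        am = np.argmin(block, axis=1)
                        block[row_idx, am] = np.inf
                    kth[c] = block[row_idx, np.argmin(block, axis=1)]
                # distance tie between the class medians -> lower class code
                pred = (kth[1] < kth[0]).astype(np.int64)
            else:  # even k: explicit top-k vote, nearest-neighbour tie break
                near = np.argpartition(flat, kth=k - 1, axis=1)[:, :k]
                votes = ys[near].sum(axis=1)
                pred = (2 * votes > k).astype(np.int64)
                tie = 2 * votes == k
                if np.any(tie):
                    pred[tie] = ys[np.argmin(flat[tie], axis=1)]
            correct = pred.reshape(B, n_trials) == ys[None, :]
            acc_cols[sel] = correct.mean(axis=1)

    values = np.full(grid.shape, np.nan)
    values[mask] = acc_cols
    counts = {tp: int(np.sum(y == code)) for tp, code in _TP_CODE.items()}
    meta = {
        "radius_mm": spheres.radius_mm,
        "k": k,
        "cv": "leave-one-participant-out",
        "n_participants": len(pattern_sets),
        "n_trials_per_class": counts,
        "n_predictions": int(n_trials),
        "participants": [ps.participant for ps in pattern_sets],
    }
    groups = {ps.group for ps in pattern_sets}
    group = groups.pop() if len(groups) == 1 else "mixed"
    return AccuracyMap(grid=grid, values=values, mask=mask, group=group, meta=meta)


def accuracy_to_nifti(acc: AccuracyMap, path) -> None:
    """Write the accuracy map as NIfTI plus a JSON sidecar."""
    nib.save(nib.Nifti1Image(acc.values.astype(np.float32), acc.grid.affine), str(path))
    sidecar = dict(acc.meta)
    sidecar["group"] = acc.group
    sidecar_path = str(path).replace(".nii.gz", "").replace(".nii", "") + ".json"
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)


def accuracy_from_nifti(path) -> AccuracyMap:
    img = nib.load(str(path))
    values = np.asanyarray(img.dataobj, dtype=float)
    grid = VoxelGrid.from_affine(values.shape, img.affine)
    sidecar_path = str(path).replace(".nii.gz", "").replace(".nii", "") + ".json"
    try:
        with open(sidecar_path) as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        meta = {}
    group = meta.pop("group", "")
    mask = np.isfinite(values)
    return AccuracyMap(grid=grid, values=values, mask=mask, group=group, meta=meta)
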