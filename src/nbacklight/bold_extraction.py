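"""First-level contrast maps and trial-wise BOLD patterns.

Two read-outs are computed from a session's 4D BOLD series and its task
design:

* the **univariate path** — a per-voxel ordinary-least-squares fit of the
  signal on HRF-convolved level regressors (plus intercept and a linear
  drift), from which named contrast maps such as "2>0" are formed and
  optionally Gaussian-smoothed; and
* the **multivariate path** — per-trial evoked responses, taken as the
  mean of the volumes 2-3 TRs (4-6 s, the canonical HRF peak) after each
  stimulus onset, referenced to the session's mean 0-back response.  For
  the 2-back task this yields 42 baseline-referenced trial patterns per
  session with the default 3x16 design, the searchlight's input.

Whether the original analysis smoothed its multivariate input is not
something the pipeline assumes: smoothing is applied on the univariate
path and is available, but off, for trial patterns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import VoxelGrid
from .hrf import HRFParams, level_regressors
from .synthetic_data import Bold4D
from .task_design import NBackDesign, valid_trials

__all__ = [
    "CONTRAST_WEIGHTS",
    "ContrastMap",
    "EffectMaps",
    "TrialPatternSet",
    "smooth_gaussian",
    "fit_first_level",
    "make_contrast",
    "extract_trial_patterns",
    "contrast_to_nifti",
    "contrast_from_nifti",
]

#: Named contrast weights over n-back levels.  Task-vs-task weights sum
#: to zero; "2>rest" is the 2-back effect against the implicit baseline.
CONTRAST_WEIGHTS: dict[str, dict[int, float]] = {
    "1>0": {1: 1.0, 0: -1.0},
    "2>1": {2: 1.0, 1: -1.0},
    "2>0": {2: 1.0, 0: -1.0},
    "2>rest": {2: 1.0},
}

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_gaussian(volume, fwhm_mm: float, grid: VoxelGrid | None = None):
    """Separable Gaussian smoothing with FWHM given in millimetres.

    Accepts a 3D array (with ``grid``) or a :class:`ContrastMap`.  The
    kernel sigma per axis is ``fwhm / (2 sqrt(2 ln 2))`` mm converted to
    voxels through the grid's voxel size; ``fwhm_mm = 0`` is the
    identity.  The edge mode preserves constant volumes.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if isinstance(volume, ContrastMap):
        smoothed = smooth_gaussian(volume.values, fwhm_mm, grid=volume.grid)
        return ContrastMap(
            grid=volume.grid,
            values=smoothed,
            name=volume.name,
            participant=volume.participant,
            time_point=volume.time_point,
            mask=volume.mask,
        )
    if grid is None:
        raise ValueError("grid is required when smoothing a bare array")
    arr = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return arr
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in grid.voxel_size]
    return ndimage.gaussian_filter(arr, sigma=sigma_vox, mode="nearest")


@dataclass(eq=False)
class EffectMaps:
    """Per-level OLS coefficient maps from a first-level fit."""

    grid: VoxelGrid
    effects: dict  # level -> 3D array (0 outside mask)
    mask: np.ndarray
    participant: str
    time_point: str


@dataclass(eq=False)
class ContrastMap:
    """A per-voxel weighted combination of level effects."""

    grid: VoxelGrid
    values: np.ndarray  # 3D, 0 outside mask
    name: str
    participant: str
    time_point: str
    mask: np.ndarray | None = None


def _brain_mask_from(bold: Bold4D, mask: np.ndarray | None) -> np.ndarray:
    if mask is not None:
        if mask.shape != bold.grid.shape:
            raise ValueError("mask shape does not match the BOLD grid")
        return mask.astype(bool)
    # default: voxels that carry any temporal signal at all
    return bold.data.std(axis=3) > 0


def fit_first_level(
    bold: Bold4D,
    design: NBackDesign,
    drift: bool = True,
    hrf_params: HRFParams | None = None,
    mask: np.ndarray | None = None,
) -> EffectMaps:
    """Voxelwise OLS of the BOLD signal on HRF-convolved level regressors.

    The design matrix holds one regressor per n-back level, an intercept
    and (by default) a linear drift.  Raises a ``ValueError`` naming the
    collinear columns if the matrix is rank deficient.
    """
    n_t = bold.n_scans
    if design.duration > n_t * bold.tr:
        raise ValueError("BOLD time axis does not cover the design")
    regs = level_regressors(design, n_t, bold.tr, params=hrf_params)
    names = [f"level_{level}" for level in design.levels]
    cols = [regs[level] for level in design.levels]
    names.append("intercept")
    cols.append(np.ones(n_t))
    if drift:
        names.append("drift")
        cols.append(np.linspace(-0.5, 0.5, n_t))
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _collinear_columns(X, names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")

    bmask = _brain_mask_from(bold, mask)
    Y = bold.data[bmask].T.astype(float)  # (n_t, n_mask)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)

    effects = {}
    for i, level in enumerate(design.levels):
        vol = np.zeros(bold.grid.shape)
        vol[bmask] = beta[i]
        effects[int(level)] = vol
    return EffectMaps(
        grid=bold.grid,
        effects=effects,
        mask=bmask,
        participant=bold.participant,
        time_point=bold.time_point,
    )


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy QR sweep: columns that do not increase the rank."""
    kept: list[int] = []
    collinear: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(j)
        else:
            collinear.append(names[j])
    return collinear


def make_contrast(effects: EffectMaps, name: str) -> ContrastMap:
    """Form a named contrast map from per-level effect maps."""
    if name not in CONTRAST_WEIGHTS:
        raise ValueError(f"unknown contrast {name!r}; expected one of {sorted(CONTRAST_WEIGHTS)}")
    weights = CONTRAST_WEIGHTS[name]
    missing = [lvl for lvl in weights if lvl not in effects.effects]
    if missing:
        raise ValueError(f"contrast {name!r} needs level effects {missing} which are absent")
    values = np.zeros(effects.grid.shape)
    for level, w in weights.items():
        values = values + w * effects.effects[level]
    return ContrastMap(
        grid=effects.grid,
        values=values,
        name=name,
        participant=effects.participant,
        time_point=effects.time_point,
        mask=effects.mask,
    )


@dataclass(eq=False)
class TrialPatternSet:
    """Labeled trial x voxel matrix for one participant.

    ``data`` has one row per trial (both time points stacked) and one
    column per in-mask voxel; ``labels`` carries ``time_point``,
    ``level``, ``block`` and ``trial`` per row.  Values are trial evoked
    responses referenced to the session's mean 0-back response.
    """

    participant: str
    group: str
    data: np.ndarray  # (n_trials, n_voxels)
    labels: pd.DataFrame
    mask: np.ndarray
    grid: VoxelGrid
    lag_window: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.labels):
            raise ValueError("label rows do not match data rows")
        if self.data.shape[1] != int(self.mask.sum()):
            raise ValueError("data columns do not match mask voxel count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial patterns contain non-finite values")

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.save(out / "patterns.npy", self.data.astype(np.float32))
        self.labels.to_csv(out / "labels.tsv", sep="\t", index=False)
        nib.save(nib.Nifti1Image(self.mask.astype(np.int8), self.grid.affine), str(out / "mask.nii.gz"))
        meta = {
            "participant": self.participant,
            "group": self.group,
            "lag_window": list(self.lag_window),
            "voxel_size": list(self.grid.voxel_size),
        }
        (out / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, in_dir) -> "TrialPatternSet":
        src = Path(in_dir)
        meta = json.loads((src / "meta.json").read_text())
        mask_img = nib.load(str(src / "mask.nii.gz"))
        mask = np.asanyarray(mask_img.dataobj).astype(bool)
        grid = VoxelGrid.from_affine(mask.shape, mask_img.affine)
        return cls(
            participant=meta["participant"],
            group=meta["group"],
            data=np.load(src / "patterns.npy").astype(np.float64),
            labels=pd.read_csv(src / "labels.tsv", sep="\t"),
            mask=mask,
            grid=grid,
            lag_window=tuple(meta["lag_window"]),
        )


def _trial_responses(bold: Bold4D, onsets: np.ndarray, lag_window, mask: np.ndarray) -> np.ndarray:
    """Mean of the volumes at ``floor(onset/TR) + lag`` per onset; (n_onsets, n_mask)."""
    lags = np.asarray(lag_window, dtype=int)
    onset_tr = np.floor(onsets / bold.tr).astype(int)
    if (onset_tr[:, None] + lags[None, :]).max() >= bold.n_scans:
        raise ValueError(
            f"lag window {tuple(lag_window)} extends past the end of the time series "
            f"({bold.n_scans} volumes)"
        )
    flat = bold.data[mask].astype(float)  # (n_mask, n_t)
    out = np.empty((onsets.size, flat.shape[0]))
    for i, t0 in enumerate(onset_tr):
        out[i] = flat[:, t0 + lags].mean(axis=1)
    return out


def extract_trial_patterns(
    bold_baseline: Bold4D,
    bold_followup: Bold4D,
    design: NBackDesign,
    levels: tuple[int, ...] = (2,),
    lag_window: tuple[int, ...] = (2, 3),
    mask: np.ndarray | None = None,
) -> TrialPatternSet:
    """Build the 0-back-referenced trial x voxel matrix across time points.

    For every requested level, each valid trial (within-block index >=
    level) contributes one row per session: the mean of the volumes
    ``lag_window`` TRs after its onset, minus the session's mean response
    over all 0-back trials computed with the same window.  Rows are
    labeled with time point, level, block and trial index.
    """
    if bold_baseline.grid != bold_followup.grid:
        raise ValueError("both sessions must share the voxel grid")
    if bold_baseline.participant != bold_followup.participant:
        raise ValueError("sessions belong to different participants")
    if 0 not in design.levels:
        raise ValueError("the design has no 0-back blocks to reference against")
    for level in levels:
        if level not in design.levels:
            raise ValueError(f"level {level} not in design levels {design.levels}")

    bmask = _brain_mask_from(bold_baseline, mask) & _brain_mask_from(bold_followup, mask)
    table = design.table
    zero_onsets = table.loc[table["level"] == 0, "onset_s"].to_numpy()

    blocks_data = []
    label_rows = []
    for tp, bold in (("baseline", bold_baseline), ("followup", bold_followup)):
        ref = _trial_responses(bold, zero_onsets, lag_window, bmask).mean(axis=0)
        for level in levels:
            sel = table[(table["level"] == level) & (table["index"] >= level)]
            resp = _trial_responses(bold, sel["onset_s"].to_numpy(), lag_window, bmask)
            blocks_data.append(resp - ref[None, :])
            for _, row in sel.iterrows():
                label_rows.append(
                    {
                        "time_point": tp,
                        "level": int(level),
                        "block": int(row["block"]),
                        "trial": int(row["index"]),
                    }
                )

    data = np.vstack(blocks_data)
    labels = pd.DataFrame(label_rows)
    for level in levels:
        per_tp = valid_trials(design, level)
        for tp in ("baseline", "followup"):
            got = int(((labels["time_point"] == tp) & (labels["level"] == level)).sum())
            assert got == per_tp, f"{tp}/{level}: {got} rows != valid_trials {per_tp}"
    return TrialPatternSet(
        participant=bold_baseline.participant,
        group=bold_baseline.group,
        data=data,
        labels=labels,
        mask=bmask,
        grid=bold_baseline.grid,
        lag_window=tuple(lag_window),
    )


def cohort_patterns(
    spec,
    levels: tuple[int, ...] = (2,),
    lag_window: tuple[int, ...] = (2, 3),
    group: str | None = None,
    mask: np.ndarray | None = None,
) -> list[TrialPatternSet]:
    """Simulate a cohort session-by-session and extract trial patterns.

    Streams through participants (optionally one group only) so that no
    more than two 4D volumes are alive at a time; returns one
    :class:`TrialPatternSet` per participant, the searchlight's input.
    """
    from .synthetic_data import simulate_subject

    out = []
    for pid, grp in spec.participants():
        if group is not None and grp != group:
            continue
        bold_base, _ = simulate_subject(spec, pid, "baseline")
        bold_fu, _ = simulate_subject(spec, pid, "followup")
        out.append(
            extract_trial_patterns(
                bold_base, bold_fu, spec.design, levels=levels, lag_window=lag_window, mask=mask
            )
        )
    return out


def contrast_to_nifti(cmap: ContrastMap, path) -> None:
    nib.save(nib.Nifti1Image(cmap.values.astype(np.float32), cmap.grid.affine), str(path))


def contrast_from_nifti(path, name: str = "", participant: str = "", time_point: str = "") -> ContrastMap:
    img = nib.load(str(path))
    values = np.asanyarray(img.dataobj, dtype=float)
    grid = VoxelGrid.from_affine(values.shape, img.affine)
    return ContrastMap(grid=grid, values=values, name=name, participant=participant, time_point=time_point)
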