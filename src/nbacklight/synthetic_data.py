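"""Synthetic two-group, two-time-point n-back fMRI study generator.

The generator emulates the measurement situation of a longitudinal
working-memory study in sickle cell disease: a treated and an untreated
control group, each scanned at baseline and at ~1-year follow-up while
performing a blocked 0/1/2-back task (TR = 2 s).  Every session is a 4D
BOLD volume on a common, already-normalised grid:

``signal(v, t) = baseline
               + sum_levels amplitude[level] * regressor_level(t)
               + pattern(v) * regressor_2back(t)
               + noise(v, t)``

where ``pattern`` is a participant-specific multivoxel pattern (drawn
once per participant, fixed across that participant's trials) riding on
the highest-load regressor, and ``noise`` is i.i.d. Gaussian (an AR(1)
option exists).  A *time-point effect* is injected through spherical
clusters: inside a cluster assigned to a group, the follow-up pattern of
every participant in that group is the baseline pattern plus a Gaussian
shift field.  The shift field is drawn once per cluster and shared by
the group's participants, so that leave-one-participant-out decoding of
time points has a signal that generalises across participants; what is
participant-specific is the baseline pattern itself.

Matching behavioral responses are drawn from a per-group, per-time-point
omission/commission model; by default the control group's follow-up
omission rate is elevated, mirroring the behavioural asymmetry the
analysis pipeline is meant to detect.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import VoxelGrid
from .hrf import HRFParams, canonical_hrf, level_regressors  # noqa: F401  (canonical_hrf re-exported)
from .task_design import NBackDesign, design_to_tsv, generate_design

__all__ = [
    "GROUPS",
    "TIME_POINTS",
    "canonical_hrf",
    "InjectedCluster",
    "BehaviorModel",
    "SimulationSpec",
    "Bold4D",
    "Cohort",
    "brain_mask",
    "cluster_masks",
    "cluster_label_volume",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
    "bold_to_nifti",
    "bold_from_nifti",
]

GROUPS = ("control", "treated")  # group codes: control=0, treated=1
TIME_POINTS = ("baseline", "followup")

# rng stream tags so that (seed, participant, time point) fully determine output
_TAG_SHIFT, _TAG_PATTERN, _TAG_SESSION = 101, 211, 307


@dataclass(frozen=True)
class InjectedCluster:
    """A spherical region where follow-up patterns differ from baseline.

    ``center_vox`` is a voxel index triple, ``radius_mm`` a world-space
    radius, ``group`` the group whose participants receive the shift and
    ``pattern_shift_sd`` the per-voxel SD of the shared shift field.
    """

    center_vox: tuple[int, int, int]
    radius_mm: float
    group: str
    pattern_shift_sd: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("cluster radius must be positive")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.pattern_shift_sd < 0:
            raise ValueError("pattern_shift_sd must be non-negative")


def _default_p_omission() -> dict:
    return {
        "treated": {"baseline": 0.15, "followup": 0.15},
        "control": {"baseline": 0.15, "followup": 0.35},
    }


def _default_p_commission() -> dict:
    return {
        "treated": {"baseline": 0.05, "followup": 0.05},
        "control": {"baseline": 0.05, "followup": 0.05},
    }


@dataclass(frozen=True)
class BehaviorModel:
    """Lapse/guess response model per group and time point.

    Targets are answered with probability ``1 - p_omission[group][tp]``;
    nontargets draw a false response with ``p_commission[group][tp]``.
    Reaction times are Gaussian (mean 0.55 s, SD 0.12 s) clipped to the
    response window.  The default elevates control-group omissions at
    follow-up, the behavioural change the study design is sensitive to.
    """

    p_omission: dict = field(default_factory=_default_p_omission)
    p_commission: dict = field(default_factory=_default_p_commission)
    rt_mean: float = 0.55
    rt_sd: float = 0.12
    rt_bounds: tuple[float, float] = (0.15, 1.9)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rt_bounds", tuple(self.rt_bounds))
        for table in (self.p_omission, self.p_commission):
            for group in GROUPS:
                for tp in TIME_POINTS:
                    p = table[group][tp]
                    if not (0.0 <= p <= 1.0):
                        raise ValueError(f"probability {p} for {group}/{tp} not in [0, 1]")


def _default_amplitudes() -> dict:
    # monotone load response: higher working-memory load, larger evoked peak
    return {0: 1.0, 1: 1.5, 2: 2.0}


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a synthetic study.

    Defaults mirror the study conditions: 13 treated and 8 control
    participants with imaging at both time points, the 3x16/4-target
    0-1-2-back design, TR = 2 s.  The default 24x28x24 grid at 3 mm is a
    desk-scale stand-in for a normalised whole-brain volume (the native
    64x64x32 grid is supported by passing a different ``grid``).
    """

    grid: VoxelGrid = field(default_factory=lambda: VoxelGrid((24, 28, 24)))
    n_treated: int = 13
    n_control: int = 8
    design: NBackDesign = field(default_factory=lambda: generate_design(seed=0))
    tr: float = 2.0
    hrf: HRFParams = field(default_factory=HRFParams)
    noise_sd: float = 1.0
    ar_coef: float = 0.0
    baseline: float = 100.0
    amplitudes: dict = field(default_factory=_default_amplitudes)
    pattern_sd: float = 0.5
    injected_clusters: tuple[InjectedCluster, ...] = ()
    behavior: BehaviorModel = field(default_factory=BehaviorModel)
    seed: int = 0
    tail_duration: float = 16.0  # post-task padding so late HRFs fit in the scan
    brain_axis_frac: float = 0.9  # ellipsoid semi-axes as fraction of half-shape

    def __post_init__(self) -> None:
        for name, n in (("n_treated", self.n_treated), ("n_control", self.n_control)):
            if n != 0 and n < 2:
                raise ValueError(
                    f"{name} must be 0 or >= 2 (leave-one-participant-out needs >= 2)"
                )
        if self.n_treated == 0 and self.n_control == 0:
            raise ValueError("at least one group must have participants")
        if self.tr <= 0 or self.noise_sd < 0 or self.pattern_sd < 0:
            raise ValueError("tr must be positive; noise_sd and pattern_sd non-negative")
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must be in [0, 1)")
        object.__setattr__(self, "injected_clusters", tuple(self.injected_clusters))
        unknown = set(self.amplitudes) - set(self.design.levels)
        if unknown:
            raise ValueError(f"amplitudes given for levels not in the design: {sorted(unknown)}")

    @property
    def n_scans(self) -> int:
        return int(math.ceil((self.design.duration + self.tail_duration) / self.tr))

    def participants(self) -> list[tuple[str, str]]:
        """(participant id, group) pairs; controls first, group code order."""
        out = [(f"control_{i:02d}", "control") for i in range(self.n_control)]
        out += [(f"treated_{i:02d}", "treated") for i in range(self.n_treated)]
        return out


def brain_mask(spec: SimulationSpec) -> np.ndarray:
    """Ellipsoidal in-brain mask on the spec's grid."""
    shape = spec.grid.shape
    center = [(s - 1) / 2.0 for s in shape]
    axes = [max(spec.brain_axis_frac * (s - 1) / 2.0, 0.5) for s in shape]
    idx = np.indices(shape, dtype=float)
    r2 = sum(((idx[a] - center[a]) / axes[a]) ** 2 for a in range(3))
    return r2 <= 1.0


def cluster_masks(spec: SimulationSpec) -> list[np.ndarray]:
    """Boolean mask per injected cluster (intersected with the brain mask)."""
    bm = brain_mask(spec)
    idx = np.indices(spec.grid.shape, dtype=float)
    vs = np.asarray(spec.grid.voxel_size)
    out = []
    for cluster in spec.injected_clusters:
        d2 = sum(((idx[a] - cluster.center_vox[a]) * vs[a]) ** 2 for a in range(3))
        out.append((d2 <= cluster.radius_mm**2) & bm)
    return out


def cluster_label_volume(spec: SimulationSpec) -> np.ndarray:
    """Ground-truth label volume: voxel value i marks injected cluster i (1-based)."""
    labels = np.zeros(spec.grid.shape, dtype=np.int16)
    for i, mask in enumerate(cluster_masks(spec), start=1):
        labels[mask] = i
    return labels


@dataclass(eq=False)
class Bold4D:
    """One session's 4D BOLD data with its acquisition metadata."""

    grid: VoxelGrid
    tr: float
    data: np.ndarray  # (x, y, z, t)
    participant: str
    group: str
    time_point: str

    def __post_init__(self) -> None:
        if self.data.shape[:3] != self.grid.shape:
            raise ValueError("data spatial shape does not match grid")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")

    @property
    def n_scans(self) -> int:
        return self.data.shape[3]


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(tuple(int(k) for k in key)))


def _participant_index(spec: SimulationSpec, participant: str) -> int:
    ids = [pid for pid, _ in spec.participants()]
    try:
        return ids.index(participant)
    except ValueError:
        raise ValueError(f"unknown participant {participant!r}") from None


def _pattern_for(spec: SimulationSpec, participant: str, group: str, time_point: str, mask: np.ndarray) -> np.ndarray:
    """Participant multivoxel pattern over mask voxels for one time point."""
    p_idx = _participant_index(spec, participant)
    n_mask = int(mask.sum())
    pattern = spec.pattern_sd * _rng(spec.seed, _TAG_PATTERN, p_idx).standard_normal(n_mask)
    if time_point == "followup":
        col_of = np.full(spec.grid.shape, -1, dtype=np.int64)
        col_of[mask] = np.arange(n_mask)
        for c_idx, (cluster, cmask) in enumerate(zip(spec.injected_clusters, cluster_masks(spec))):
            if cluster.group != group:
                continue
            shift_rng = _rng(spec.seed, _TAG_SHIFT, c_idx)
            shift = cluster.pattern_shift_sd * shift_rng.standard_normal(int(cmask.sum()))
            cols = col_of[cmask]
            keep = cols >= 0
            pattern[cols[keep]] += shift[keep]
    return pattern


def _draw_responses(spec: SimulationSpec, group: str, time_point: str, rng: np.random.Generator) -> pd.DataFrame:
    beh = spec.behavior
    p_om = beh.p_omission[group][time_point]
    p_com = beh.p_commission[group][time_point]
    table = spec.design.table[["block", "level", "index", "onset_s", "is_target"]].copy()
    is_target = table["is_target"].to_numpy(dtype=bool)
    u = rng.random(len(table))
    responded = np.where(is_target, u < 1.0 - p_om, u < p_com)
    rt = np.clip(rng.normal(beh.rt_mean, beh.rt_sd, len(table)), *beh.rt_bounds)
    table["responded"] = responded
    table["rt_s"] = np.where(responded, rt, np.nan)
    return table


def simulate_subject(spec: SimulationSpec, participant: str, time_point: str) -> tuple[Bold4D, pd.DataFrame]:
    """Simulate one session: a 4D BOLD volume plus its response table.

    Output is bit-identical for identical ``(spec, participant,
    time_point)`` and independent of any other session that has been
    generated: every random draw is keyed on the spec seed, the
    participant index and the time point.
    """
    if time_point not in TIME_POINTS:
        raise ValueError(f"time_point must be one of {TIME_POINTS}")
    p_idx = _participant_index(spec, participant)
    group = dict(spec.participants())[participant]
    tp_idx = TIME_POINTS.index(time_point)

    n_t = spec.n_scans
    regs = level_regressors(spec.design, n_t, spec.tr, params=spec.hrf)
    mask = brain_mask(spec)
    n_mask = int(mask.sum())

    task = np.zeros(n_t)
    for level, amp in spec.amplitudes.items():
        task += amp * regs[int(level)]
    top_level = max(spec.design.levels)

    signal = np.empty((n_mask, n_t))
    signal[:] = spec.baseline + task
    pattern = _pattern_for(spec, participant, group, time_point, mask)
    signal += pattern[:, None] * regs[top_level][None, :]

    rng = _rng(spec.seed, _TAG_SESSION, p_idx, tp_idx)
    if spec.noise_sd > 0:
        noise = rng.standard_normal((n_mask, n_t))
        if spec.ar_coef > 0:
            a = spec.ar_coef
            for t in range(1, n_t):
                noise[:, t] = a * noise[:, t - 1] + math.sqrt(1 - a * a) * noise[:, t]
        signal += spec.noise_sd * noise

    data = np.zeros(spec.grid.shape + (n_t,), dtype=np.float32)
    data[mask] = signal
    bold = Bold4D(
        grid=spec.grid,
        tr=spec.tr,
        data=data,
        participant=participant,
        group=group,
        time_point=time_point,
    )
    responses = _draw_responses(spec, group, time_point, rng)
    return bold, responses


@dataclass(eq=False)
class Cohort:
    """An in-memory simulated study: all sessions plus ground truth."""

    spec: SimulationSpec
    sessions: dict  # (participant, time_point) -> (Bold4D, responses)
    manifest: pd.DataFrame
    ground_truth: np.ndarray  # injected-cluster label volume


def simulate_cohort(spec: SimulationSpec) -> Cohort:
    """Simulate every participant at both time points, in memory.

    Intended for desk-scale specs; at the full study size the per-session
    streaming interface (:func:`simulate_subject` or
    :func:`write_cohort`) avoids holding all volumes at once.
    """
    sessions = {}
    rows = []
    for pid, group in spec.participants():
        for tp in TIME_POINTS:
            sessions[(pid, tp)] = simulate_subject(spec, pid, tp)
            rows.append({"participant": pid, "group": group, "time_point": tp})
    return Cohort(
        spec=spec,
        sessions=sessions,
        manifest=pd.DataFrame(rows),
        ground_truth=cluster_label_volume(spec),
    )


def bold_to_nifti(bold: Bold4D, path) -> None:
    img = nib.Nifti1Image(bold.data, bold.grid.affine)
    img.header.set_zooms((*bold.grid.voxel_size, bold.tr))
    nib.save(img, str(path))


def bold_from_nifti(path, participant: str = "", group: str = "", time_point: str = "", tr: float | None = None) -> Bold4D:
    """Load a 4D NIfTI as :class:`Bold4D`; TR taken from the header unless given."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got shape {data.shape}")
    grid = VoxelGrid.from_affine(data.shape[:3], img.affine)
    zooms = img.header.get_zooms()
    tr = float(tr if tr is not None else (zooms[3] if len(zooms) > 3 else 0.0))
    if tr <= 0:
        raise ValueError(f"{path}: TR not present in header; pass tr= explicitly")
    return Bold4D(grid=grid, tr=tr, data=data, participant=participant, group=group, time_point=time_point)


def write_cohort(spec: SimulationSpec, out_dir) -> Path:
    """Simulate and write a full cohort to ``out_dir``, streaming.

    Writes per-session BOLD NIfTIs and response TSVs, a manifest TSV, the
    design TSV, the spec as JSON, and the ground-truth injected-cluster
    label volume with a JSON sidecar.  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid, group in spec.participants():
        for tp in TIME_POINTS:
            bold, responses = simulate_subject(spec, pid, tp)
            bold_file = out / f"bold_{pid}_{tp}.nii.gz"
            resp_file = out / f"responses_{pid}_{tp}.tsv"
            try:
                bold_to_nifti(bold, bold_file)
                responses.to_csv(resp_file, sep="\t", index=False)
            except OSError as err:
                raise OSError(f"failed writing session files under {out}: {err}") from err
            rows.append(
                {
                    "file": bold_file.name,
                    "responses": resp_file.name,
                    "participant": pid,
                    "group": group,
                    "time_point": tp,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest_path = out / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    design_to_tsv(spec.design, out / "design.tsv")
    (out / "spec.json").write_text(json.dumps(spec_to_dict(spec), indent=2))

    gt = cluster_label_volume(spec)
    nib.save(nib.Nifti1Image(gt, spec.grid.affine), str(out / "ground_truth_clusters.nii.gz"))
    sidecar = [
        {
            "label": i + 1,
            "center_vox": list(c.center_vox),
            "radius_mm": c.radius_mm,
            "group": c.group,
            "pattern_shift_sd": c.pattern_shift_sd,
        }
        for i, c in enumerate(spec.injected_clusters)
    ]
    (out / "ground_truth_clusters.json").write_text(json.dumps(sidecar, indent=2))
    return manifest_path


# --- flat JSON configuration --------------------------------------------


def spec_to_dict(spec: SimulationSpec) -> dict:
    """Serialise a spec to a JSON-compatible dictionary."""
    d = {
        "grid": {"shape": list(spec.grid.shape), "voxel_size": list(spec.grid.voxel_size)},
        "n_treated": spec.n_treated,
        "n_control": spec.n_control,
        "design": {
            "levels": list(spec.design.levels),
            "blocks_per_level": spec.design.blocks_per_level,
            "stimuli_per_block": spec.design.stimuli_per_block,
            "targets_per_block": spec.design.targets_per_block,
            "seed": spec.design.seed,
        },
        "tr": spec.tr,
        "hrf": dataclasses.asdict(spec.hrf),
        "noise_sd": spec.noise_sd,
        "ar_coef": spec.ar_coef,
        "baseline": spec.baseline,
        "amplitudes": {str(k): v for k, v in spec.amplitudes.items()},
        "pattern_sd": spec.pattern_sd,
        "injected_clusters": [
            {
                "center_vox": list(c.center_vox),
                "radius_mm": c.radius_mm,
                "group": c.group,
                "pattern_shift_sd": c.pattern_shift_sd,
            }
            for c in spec.injected_clusters
        ],
        "behavior": dataclasses.asdict(spec.behavior),
        "seed": spec.seed,
        "tail_duration": spec.tail_duration,
        "brain_axis_frac": spec.brain_axis_frac,
    }
    return d


def spec_from_dict(d: dict) -> SimulationSpec:
    """Inverse of :func:`spec_to_dict`."""
    grid = VoxelGrid(tuple(d["grid"]["shape"]), tuple(d["grid"]["voxel_size"]))
    des = d.get("design", {})
    design = generate_design(
        levels=tuple(des.get("levels", (0, 1, 2))),
        blocks_per_level=des.get("blocks_per_level", 3),
        stimuli_per_block=des.get("stimuli_per_block", 16),
        targets_per_block=des.get("targets_per_block", 4),
        seed=des.get("seed") if des.get("seed") is not None else d.get("seed", 0),
    )
    behavior = BehaviorModel(**d["behavior"]) if "behavior" in d else BehaviorModel()
    return SimulationSpec(
        grid=grid,
        n_treated=d.get("n_treated", 13),
        n_control=d.get("n_control", 8),
        design=design,
        tr=d.get("tr", 2.0),
        hrf=HRFParams(**d["hrf"]) if "hrf" in d else HRFParams(),
        noise_sd=d.get("noise_sd", 1.0),
        ar_coef=d.get("ar_coef", 0.0),
        baseline=d.get("baseline", 100.0),
        amplitudes={int(k): float(v) for k, v in d.get("amplitudes", {"0": 1.0, "1": 1.5, "2": 2.0}).items()},
        pattern_sd=d.get("pattern_sd", 0.5),
        injected_clusters=tuple(
            InjectedCluster(
                center_vox=tuple(c["center_vox"]),
                radius_mm=c["radius_mm"],
                group=c["group"],
                pattern_shift_sd=c["pattern_shift_sd"],
            )
            for c in d.get("injected_clusters", [])
        ),
        behavior=behavior,
        seed=d.get("seed", 0),
        tail_duration=d.get("tail_duration", 16.0),
        brain_axis_frac=d.get("brain_axis_frac", 0.9),
    )
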