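"""Block-design n-back session structure and behavioral scoring.

A session is a sequence of task blocks, one n-back level per block, in
the fixed order 0-, 1-, 2-back repeated (three repeats by default, nine
blocks total).  Each block opens with a 2 s instruction screen and a 5 s
rest, then presents 16 abstract-object stimuli (500 ms on, 1500 ms
inter-stimulus interval) of which 4 are targets.  In an n-back block
(n >= 1) a target is a stimulus identical to the one shown n trials
earlier; in the 0-back block the target is a designated cue image, coded
here as stimulus 0.

Performance is summarised per level with hit/omission and correct-
rejection/commission counts and *balanced accuracy*,

    BA = (hits/total_targets + correct_rejections/total_nontargets) / 2,

the mean of sensitivity and specificity, used because targets (12 per
level) and nontargets (36 per level) are imbalanced.  Stimuli that
cannot be targets because their n-back reference falls outside the block
are still scored as nontargets, which is what makes the nontarget count
36 rather than 36 minus the reference-less trials.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NBackDesign",
    "BehavioralScores",
    "generate_design",
    "valid_trials",
    "score_behavior",
    "score_all_levels",
    "design_to_tsv",
    "design_from_tsv",
]

_CUE_CODE = 0
_N_CODES = 20  # distinct non-cue stimulus identities


@dataclass(eq=False)
class NBackDesign:
    """The timed stimulus/target/block structure of one session.

    ``table`` holds one row per stimulus with columns ``block`` (global
    block index), ``level``, ``index`` (within-block position),
    ``onset_s`` (absolute onset in seconds), ``is_target`` and
    ``stim_code`` (abstract integer identity; 0 is the 0-back cue).
    """

    levels: tuple[int, ...]
    blocks_per_level: int
    stimuli_per_block: int
    targets_per_block: int
    stimulus_duration: float
    isi: float
    instruction_duration: float
    rest_duration: float
    block_order: list[tuple[int, int]]  # (level, repeat index) per block
    table: pd.DataFrame
    seed: int | None = None  # seed used for target placement, if generated

    @property
    def n_blocks(self) -> int:
        return len(self.block_order)

    @property
    def soa(self) -> float:
        """Stimulus-onset asynchrony: stimulus duration + ISI."""
        return self.stimulus_duration + self.isi

    @property
    def onsets(self) -> np.ndarray:
        return self.table["onset_s"].to_numpy()

    @property
    def target_flags(self) -> np.ndarray:
        return self.table["is_target"].to_numpy(dtype=bool)

    @property
    def duration(self) -> float:
        """End time of the last block (seconds)."""
        per_block = (
            self.instruction_duration
            + self.rest_duration
            + self.stimuli_per_block * self.soa
        )
        return self.n_blocks * per_block

    def validate(self) -> None:
        """Check the structural invariants of the design."""
        if self.n_blocks != len(self.levels) * self.blocks_per_level:
            raise ValueError("block count does not match levels x blocks_per_level")
        t = self.table
        for block, sub in t.groupby("block"):
            level = int(sub["level"].iloc[0])
            if int(sub["is_target"].sum()) != self.targets_per_block:
                raise ValueError(f"block {block} does not contain {self.targets_per_block} targets")
            bad = sub[(sub["is_target"]) & (sub["index"] < level)]
            if len(bad):
                raise ValueError(f"block {block} has a target before index {level}")
        onsets = self.onsets
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets are not strictly increasing")
        within = t.groupby("block")["onset_s"].diff().dropna().to_numpy()
        if not np.allclose(within, self.soa):
            raise ValueError("within-block onset spacing != stimulus_duration + isi")


def generate_design(
    levels=(0, 1, 2),
    blocks_per_level: int = 3,
    stimuli_per_block: int = 16,
    targets_per_block: int = 4,
    seed: int = 0,
    stimulus_duration: float = 0.5,
    isi: float = 1.5,
    instruction_duration: float = 2.0,
    rest_duration: float = 5.0,
) -> NBackDesign:
    """Generate a reproducible n-back session design.

    Target placement is randomised with ``seed``: in a level-n block the
    4 target positions are drawn from the within-block indices >= n, and
    stimulus identities are assigned so a target equals the stimulus n
    back (or the cue for 0-back) while nontargets never accidentally
    match their reference.

    Raises
    ------
    ValueError
        If ``targets_per_block`` exceeds the number of indices that can
        host a target at some level (``stimuli_per_block - level``).
    """
    levels = tuple(int(l) for l in levels)
    if len(levels) == 0 or any(l < 0 for l in levels):
        raise ValueError("levels must be non-negative and non-empty")
    if targets_per_block < 1 or stimuli_per_block < 1 or blocks_per_level < 1:
        raise ValueError("counts must be positive")
    for level in levels:
        if targets_per_block > stimuli_per_block - level:
            raise ValueError(
                f"infeasible design: level {level} has only "
                f"{stimuli_per_block - level} indices that can host a target, "
                f"but {targets_per_block} targets were requested"
            )

    rng = np.random.default_rng(seed)
    soa = stimulus_duration + isi
    block_order = [(level, rep) for rep in range(blocks_per_level) for level in levels]

    rows = []
    t_cursor = 0.0
    for block, (level, _rep) in enumerate(block_order):
        t_cursor += instruction_duration + rest_duration
        target_idx = set(
            rng.choice(np.arange(level, stimuli_per_block), size=targets_per_block, replace=False).tolist()
        )
        codes = np.empty(stimuli_per_block, dtype=int)
        for i in range(stimuli_per_block):
            if level == 0:
                codes[i] = _CUE_CODE if i in target_idx else int(rng.integers(1, _N_CODES + 1))
            elif i in target_idx:
                codes[i] = codes[i - level]
            else:
                c = int(rng.integers(1, _N_CODES + 1))
                while i >= level and c == codes[i - level]:
                    c = int(rng.integers(1, _N_CODES + 1))
                codes[i] = c
            rows.append(
                {
                    "block": block,
                    "level": level,
                    "index": i,
                    "onset_s": t_cursor + i * soa,
                    "is_target": i in target_idx,
                    "stim_code": int(codes[i]),
                }
            )
        t_cursor += stimuli_per_block * soa

    design = NBackDesign(
        levels=levels,
        blocks_per_level=blocks_per_level,
        stimuli_per_block=stimuli_per_block,
        targets_per_block=targets_per_block,
        stimulus_duration=stimulus_duration,
        isi=isi,
        instruction_duration=instruction_duration,
        rest_duration=rest_duration,
        block_order=block_order,
        table=pd.DataFrame(rows),
        seed=seed,
    )
    design.validate()
    return design


def valid_trials(design: NBackDesign, level: int) -> int:
    """Number of level-``level`` stimuli whose n-back reference exists.

    A stimulus at within-block index i is a valid trial iff i >= level,
    so the count is ``blocks_per_level * (stimuli_per_block - level)``
    (42 for 2-back with the default 3 x 16 design).
    """
    if level not in design.levels:
        raise ValueError(f"level {level} not in design levels {design.levels}")
    t = design.table
    return int(((t["level"] == level) & (t["index"] >= level)).sum())


@dataclass(frozen=True)
class BehavioralScores:
    """Per-participant, per-level response summary."""

    participant: str
    level: int
    reaction_time_mean: float  # seconds, over hits only (NaN if no hits)
    hits: int
    total_targets: int
    correct_rejections: int
    total_nontargets: int
    omissions: int
    commissions: int
    balanced_accuracy: float

    def __post_init__(self) -> None:
        if self.hits + self.omissions != self.total_targets:
            raise ValueError("hits + omissions must equal total_targets")
        if self.correct_rejections + self.commissions != self.total_nontargets:
            raise ValueError("correct_rejections + commissions must equal total_nontargets")
        if not (0.0 <= self.balanced_accuracy <= 1.0):
            raise ValueError("balanced accuracy out of [0, 1]")


def score_behavior(
    design: NBackDesign,
    responses: pd.DataFrame,
    level: int,
    participant: str = "",
) -> BehavioralScores:
    """Score responses for one n-back level.

    ``responses`` must contain one row per stimulus of the level's
    blocks with columns ``block``, ``index``, ``responded`` and ``rt_s``
    (reaction time in seconds, NaN when no response).  A response is any
    button press inside the 2.0 s stimulus-onset-asynchrony window.

    Raises
    ------
    ValueError
        If the level has zero targets or zero nontargets (sensitivity or
        specificity undefined), or the response table is misaligned.
    """
    if level not in design.levels:
        raise ValueError(f"level {level} not in design levels {design.levels}")
    stim = design.table[design.table["level"] == level]
    merged = stim.merge(
        responses[["block", "index", "responded", "rt_s"]],
        on=["block", "index"],
        how="left",
        validate="one_to_one",
    )
    if merged["responded"].isna().any():
        missing = merged.loc[merged["responded"].isna(), ["block", "index"]]
        raise ValueError(f"responses missing for stimuli:\n{missing}")

    is_target = merged["is_target"].to_numpy(dtype=bool)
    responded = merged["responded"].to_numpy(dtype=bool)
    total_targets = int(is_target.sum())
    total_nontargets = int((~is_target).sum())
    if total_targets == 0 or total_nontargets == 0:
        raise ValueError(
            f"level {level} has {total_targets} targets and {total_nontargets} "
            "nontargets; balanced accuracy is undefined without both"
        )

    hits = int((is_target & responded).sum())
    omissions = total_targets - hits
    commissions = int((~is_target & responded).sum())
    correct_rejections = total_nontargets - commissions
    ba = 0.5 * (hits / total_targets + correct_rejections / total_nontargets)
    hit_rts = merged.loc[is_target & responded, "rt_s"].to_numpy(dtype=float)
    rt_mean = float(np.mean(hit_rts)) if hit_rts.size else float("nan")

    return BehavioralScores(
        participant=participant,
        level=level,
        reaction_time_mean=rt_mean,
        hits=hits,
        total_targets=total_targets,
        correct_rejections=correct_rejections,
        total_nontargets=total_nontargets,
        omissions=omissions,
        commissions=commissions,
        balanced_accuracy=ba,
    )


def score_all_levels(design: NBackDesign, responses: pd.DataFrame, participant: str = "") -> pd.DataFrame:
    """Score every level of the design; one row per level."""
    rows = []
    for level in design.levels:
        s = score_behavior(design, responses, level, participant=participant)
        rows.append(vars(s))
    return pd.DataFrame(rows)


# --- tab-separated on-disk representation -------------------------------

_META_FIELDS = (
    "levels",
    "blocks_per_level",
    "stimuli_per_block",
    "targets_per_block",
    "stimulus_duration",
    "isi",
    "instruction_duration",
    "rest_duration",
)


def design_to_tsv(design: NBackDesign, path) -> None:
    """Write the design table as TSV with parameter header comments."""
    with open(path, "w") as fh:
        for name in _META_FIELDS:
            value = getattr(design, name)
            if name == "levels":
                value = ",".join(str(v) for v in value)
            fh.write(f"# {name}={value}\n")
        if design.seed is not None:
            fh.write(f"# seed={design.seed}\n")
        design.table.to_csv(fh, sep="\t", index=False)


def design_from_tsv(path) -> NBackDesign:
    """Read a design written by :func:`design_to_tsv`."""
    meta: dict[str, str] = {}
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value
            else:
                body.append(line)
    table = pd.read_csv(io.StringIO("".join(body)), sep="\t")
    table["is_target"] = table["is_target"].astype(bool)
    levels = tuple(int(v) for v in meta["levels"].split(","))
    blocks_per_level = int(meta["blocks_per_level"])
    block_order = [(lvl, rep) for rep in range(blocks_per_level) for lvl in levels]
    design = NBackDesign(
        levels=levels,
        blocks_per_level=blocks_per_level,
        stimuli_per_block=int(meta["stimuli_per_block"]),
        targets_per_block=int(meta["targets_per_block"]),
        stimulus_duration=float(meta["stimulus_duration"]),
        isi=float(meta["isi"]),
        instruction_duration=float(meta["instruction_duration"]),
        rest_duration=float(meta["rest_duration"]),
        block_order=block_order,
        table=table,
        seed=int(meta["seed"]) if "seed" in meta else None,
    )
    design.validate()
    return design
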