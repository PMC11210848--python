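"""Canonical hemodynamic response function and task regressors.

The BOLD response to a brief neural event is modelled with the standard
double-gamma HRF: a gamma density peaking ~5 s after the event minus a
scaled gamma density modelling the late undershoot.  Task regressors are
built by convolving per-level stimulus boxcars with this kernel on a fine
time lattice and sampling at volume acquisition times; each regressor is
scaled so that an isolated stimulus evokes a unit-peak response, making
activation amplitudes directly interpretable in signal units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["HRFParams", "canonical_hrf", "sample_hrf", "level_regressors"]


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF shape parameters (seconds).

    ``peak_delay``/``peak_disp`` set the gamma of the positive lobe
    (shape = delay/dispersion, scale = dispersion), ``undershoot_delay``/
    ``undershoot_disp`` the negative lobe, and ``ratio`` the peak-to-
    undershoot amplitude ratio.  Defaults match the widely used canonical
    form (peak near 5 s, undershoot near 15 s).
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    ratio: float = 6.0

    def __post_init__(self) -> None:
        for name in ("peak_delay", "undershoot_delay", "peak_disp", "undershoot_disp", "ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"HRF parameter {name} must be positive")


def canonical_hrf(t, params: HRFParams | None = None) -> np.ndarray:
    """Evaluate the double-gamma HRF at times ``t`` (seconds, >= 0).

    Returns the difference of two gamma densities,
    ``g(t; peak) - g(t; undershoot) / ratio``; zero for ``t < 0`` and at
    ``t = 0`` (both gamma shapes exceed 1 with default parameters).
    """
    p = params or HRFParams()
    t = np.asarray(t, dtype=float)
    peak = stats.gamma.pdf(t, a=p.peak_delay / p.peak_disp, scale=p.peak_disp)
    under = stats.gamma.pdf(t, a=p.undershoot_delay / p.undershoot_disp, scale=p.undershoot_disp)
    out = peak - under / p.ratio
    return np.where(t >= 0, out, 0.0)


def sample_hrf(dt: float = 0.1, duration: float = 32.0, params: HRFParams | None = None) -> np.ndarray:
    """Sample the HRF on a ``dt``-spaced lattice over [0, duration)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration, dt)
    return canonical_hrf(t, params)


def _event_response(stim_duration: float, dt: float, hrf: np.ndarray) -> np.ndarray:
    """Convolved response of a single stimulus boxcar with the HRF."""
    width = max(1, int(round(stim_duration / dt)))
    boxcar = np.ones(width)
    return np.convolve(boxcar, hrf) * dt


def level_regressors(
    design,
    n_scans: int,
    tr: float,
    dt: float = 0.1,
    params: HRFParams | None = None,
) -> dict[int, np.ndarray]:
    """HRF-convolved regressor per n-back level, sampled at volume times.

    Parameters
    ----------
    design
        An :class:`~nbacklight.task_design.NBackDesign`.
    n_scans
        Number of acquired volumes.
    tr
        Repetition time in seconds.
    dt
        Internal convolution resolution in seconds.

    Returns a mapping ``level -> (n_scans,)`` array.  Regressors are
    normalised so an isolated stimulus peaks at 1.0; within a block,
    overlapping responses sum to a plateau of a few units.
    """
    hrf = sample_hrf(dt=dt, params=params)
    scale = _event_response(design.stimulus_duration, dt, hrf).max()
    n_fine = int(np.ceil(n_scans * tr / dt)) + hrf.size
    width = max(1, int(round(design.stimulus_duration / dt)))
    scan_idx = np.round(np.arange(n_scans) * tr / dt).astype(int)

    out: dict[int, np.ndarray] = {}
    table = design.table
    for level in design.levels:
        neural = np.zeros(n_fine)
        onsets = table.loc[table["level"] == level, "onset_s"].to_numpy()
        for onset in onsets:
            i0 = int(round(onset / dt))
            neural[i0 : i0 + width] = 1.0
        conv = np.convolve(neural, hrf)[:n_fine] * dt / scale
        out[int(level)] = conv[scan_idx]
    return out
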