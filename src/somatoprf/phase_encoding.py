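"""Lag-based phase-encoding analysis.

A reference time course — a boxcar responding to the first TR of each
stimulus cycle, convolved with a gamma kernel — is circularly shifted in
TR increments to produce one lagged reference per possible phase.  Each
voxel is assigned, winner-take-all, the lag whose reference correlates
best with its time series; voxels whose maximum correlation does not
exceed a threshold (default 0.25) are excluded.  Forward- and
backward-order runs are combined by mapping backward lags into the forward
phase convention and averaging circularly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hemodynamics import FINE_DT, _block_taps, gamma_kernel
from .space import BACKWARD, FORWARD, HandSpace, StimulusDesign

__all__ = [
    "LagAssignment",
    "build_lagged_references",
    "assign_lags",
    "combine_directions",
    "lag_to_digit",
    "null_inclusion_fraction",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.25


@dataclass(frozen=True)
class LagAssignment:
    """Winner-take-all phase assignment for one voxel."""

    voxel_id: int
    best_lag: float          # seconds, 0 <= lag < cycle length
    max_r: float
    included: bool
    direction: str           # forward | backward | combined


def build_lagged_references(design: StimulusDesign, tr: float | None = None,
                            gamma_shape: float = 6.0,
                            gamma_scale: float = 1.0) -> np.ndarray:
    """Lagged reference matrix, shape (n_lags, n_timebins).

    Reference 0 is a boxcar active during the first TR of each cycle,
    circularly convolved (over the cycle) with a single-gamma kernel
    (peak ~5 s by default); reference k is reference 0 shifted by k TRs.
    The number of references equals cycle length / TR.
    """
    tr = design.tr if tr is None else tr
    bins = design.seconds_per_location / tr
    if abs(bins - round(bins)) > 1e-9:
        raise ValueError("design does not tile into whole TRs per location")
    n_lags = design.cycle_bins
    taps = _block_taps(gamma_kernel(FINE_DT, gamma_shape, gamma_scale), tr, FINE_DT)
    # circular response of a one-TR pulse at cycle position 0: fold the taps
    ref0 = np.zeros(n_lags)
    for j, g in enumerate(taps):
        ref0[j % n_lags] += g
    refs = np.stack([np.roll(ref0, k) for k in range(n_lags)])
    return np.tile(refs, (1, design.n_cycles))


def assign_lags(bold: np.ndarray, references: np.ndarray,
                tr: float = 2.0, threshold: float = DEFAULT_THRESHOLD,
                direction: str = FORWARD,
                voxel_ids: Sequence[int] | None = None) -> list[LagAssignment]:
    """Winner-take-all lag per voxel from Pearson correlation with references.

    Ties are broken toward the smaller lag.  A zero-variance voxel has no
    defined correlation: it is marked not-included with max_r = 0.
    """
    bold = np.atleast_2d(np.asarray(bold, dtype=float))
    if bold.shape[1] != references.shape[1]:
        raise ValueError("bold and references differ in time length")
    if voxel_ids is None:
        voxel_ids = range(bold.shape[0])
    ref_z = references - references.mean(axis=1, keepdims=True)
    ref_norm = np.linalg.norm(ref_z, axis=1)
    bold_z = bold - bold.mean(axis=1, keepdims=True)
    bold_norm = np.linalg.norm(bold_z, axis=1)
    degenerate = bold_norm == 0
    safe_norm = np.where(degenerate, 1.0, bold_norm)
    r = (bold_z @ ref_z.T) / (safe_norm[:, None] * ref_norm[None, :])
    out = []
    for i, vid in enumerate(voxel_ids):
        if degenerate[i]:
            logger.warning("voxel %s has zero variance; excluded", vid)
            out.append(LagAssignment(vid, 0.0, 0.0, False, direction))
            continue
        k = int(np.argmax(r[i]))  # argmax returns the first (smallest) lag on ties
        max_r = float(r[i, k])
        out.append(LagAssignment(vid, k * tr, max_r, max_r > threshold, direction))
    return out


def _circular_mean_lag(l1: float, l2: float, cycle: float) -> float:
    a = 2.0 * np.pi * np.array([l1, l2]) / cycle
    s, c = np.sin(a).mean(), np.cos(a).mean()
    if np.hypot(s, c) < 1e-12:
        # antipodal lags: no unique mean; keep the first (forward) lag
        return l1 % cycle
    lag = (np.arctan2(s, c) / (2.0 * np.pi) * cycle) % cycle
    if cycle - lag < 1e-9:  # snap the wrap point to zero
        lag = 0.0
    return float(lag)


def combine_directions(forward: Sequence[LagAssignment],
                       backward: Sequence[LagAssignment],
                       design: StimulusDesign) -> list[LagAssignment]:
    """Average forward and backward lags in the forward phase convention.

    A backward lag maps to the equivalent forward phase as
    (cycle_length - lag) mod cycle_length; the two phases are then averaged
    circularly.  A voxel is included only if both directions included it;
    voxels present in one direction only are dropped with a warning.
    """
    cycle = design.cycle_seconds
    fwd = {a.voxel_id: a for a in forward}
    bwd = {a.voxel_id: a for a in backward}
    missing = set(fwd) ^ set(bwd)
    for vid in sorted(missing):
        logger.warning("voxel %s present in one direction only; excluded", vid)
    out = []
    for vid in sorted(set(fwd) & set(bwd)):
        f, b = fwd[vid], bwd[vid]
        b_equiv = (cycle - b.best_lag) % cycle
        lag = _circular_mean_lag(f.best_lag, b_equiv, cycle)
        out.append(LagAssignment(
            voxel_id=vid,
            best_lag=float(lag),
            max_r=float(0.5 * (f.max_r + b.max_r)),
            included=bool(f.included and b.included),
            direction="combined",
        ))
    return out


def lag_to_digit(assignment: LagAssignment, design: StimulusDesign,
                 space: HandSpace, delay_offset: float = 0.0) -> str:
    """Label of the location whose stimulation window contains the lag.

    Lags are interpreted in the forward phase convention (backward-direction
    assignments are mapped first).  ``delay_offset`` seconds are subtracted
    before windowing to compensate a known hemodynamic delay (default 0).
    """
    if not assignment.included:
        raise ValueError("cannot map a not-included assignment to a digit")
    if design.space != space:
        raise ValueError("design was built on a different hand space")
    cycle = design.cycle_seconds
    lag = assignment.best_lag
    if assignment.direction == BACKWARD:
        lag = (cycle - lag) % cycle
    lag = (lag - delay_offset) % cycle
    idx = int(lag // design.seconds_per_location)
    idx = min(idx, design.n_locations - 1)
    return design.labels[idx]


def null_inclusion_fraction(references: np.ndarray, n_voxels: int = 1000,
                            threshold: float = DEFAULT_THRESHOLD,
                            seed: int = 0) -> float:
    """Monte-Carlo estimate of the inclusion rate for pure-noise voxels.

    Used to sanity-check the correlation threshold against the number of
    time-bins and references of a given design.
    """
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_voxels, references.shape[1]))
    assignments = assign_lags(noise, references, threshold=threshold)
    return float(np.mean([a.included for a in assignments]))
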