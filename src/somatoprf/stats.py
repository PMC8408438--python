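"""Map-level somatotopy statistics.

Implements the overlap and pRF-characteristic statistics used to summarize
digit maps across participants:

* Dice coefficient D = 2|A n B| / (|A| + |B|) between voxel sets, and the
  (participants x digits)^2 Dice matrix with digit-major block structure.
* Map dominance ratio (MDR): mean intradigit (cross-participant,
  same-digit) Dice divided by mean interdigit Dice, with a permutation
  null that shuffles digit labels independently within each participant.
* Suppression index SI = (beta_i * x_i * y_i) / (beta_e * x_e * y_e) for
  DoG pRFs — the ratio of inhibitory to excitatory Gaussian volumes, where
  x_e = sigma_x, y_e = sigma_y and x_i = sigma_x + sigma_d,
  y_i = sigma_y + sigma_d.
* Relative activation volume per digit, peak-voxel distances normalized by
  the D1 -> Palm distance, and hand-space coverage maps.
* Pearson width-volume correlations and paired t-tests, both with
  bootstrap resampling over participants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .fitting import VoxelFitResult
from .prf_model import DOG, PRFParameters, prf_profile
from .space import DIGIT_LABELS, HandSpace

__all__ = [
    "DiceMatrix",
    "MDRResult",
    "CoverageMap",
    "dice",
    "build_dice_matrix",
    "mdr",
    "mdr_permutation_test",
    "suppression_index",
    "relative_volume",
    "peak_distances",
    "coverage_map",
    "width_volume_correlation",
    "paired_bootstrap_test",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Dice matrix and dominance ratio

@dataclass
class DiceMatrix:
    """Square symmetric Dice matrix over (participant, digit) map pairs.

    Rows are ordered digit-major: all participants of digit 1, then all
    participants of digit 2, ... so same-digit blocks are contiguous.
    """

    matrix: np.ndarray
    row_labels: list[tuple[int, str]]
    n_participants: int
    n_digits: int

    @property
    def digits(self) -> list[str]:
        return [self.row_labels[d * self.n_participants][1] for d in range(self.n_digits)]

    def block(self, a: int, b: int) -> np.ndarray:
        """(participants x participants) submatrix for digit pair (a, b)."""
        P = self.n_participants
        return self.matrix[a * P:(a + 1) * P, b * P:(b + 1) * P]


@dataclass
class MDRResult:
    """Map dominance ratio with its permutation null."""

    mdr: float
    n_permutations: int
    p_value: float
    permuted_mdrs: np.ndarray


@dataclass
class CoverageMap:
    """Group-average normalized pRF coverage of the hand space, in [0, 1]."""

    grid: np.ndarray
    roi: str | None
    n_voxels: int


def _as_bool(a) -> np.ndarray:
    arr = np.asarray(a)
    if arr.dtype != bool:
        arr = arr.astype(bool)
    return arr


def dice(a, b) -> float:
    """Dice overlap coefficient 2|A n B| / (|A| + |B|), in [0, 1].

    Accepts boolean membership arrays over a common voxel universe, or any
    iterables of voxel ids.  Undefined (error) when both sets are empty.
    """
    if isinstance(a, np.ndarray) and isinstance(b, np.ndarray):
        a, b = _as_bool(a), _as_bool(b)
        if a.shape != b.shape:
            raise ValueError("voxel sets live on different universes")
        na, nb = int(a.sum()), int(b.sum())
        inter = int((a & b).sum())
    else:
        sa, sb = set(a), set(b)
        na, nb = len(sa), len(sb)
        inter = len(sa & sb)
    if na + nb == 0:
        raise ValueError("Dice undefined for two empty sets")
    return 2.0 * inter / (na + nb)


def build_dice_matrix(maps: Mapping[tuple[int, str], np.ndarray]) -> DiceMatrix:
    """Dice matrix over all (participant, digit) pairings, digit-major order."""
    participants = sorted({p for p, _ in maps})
    digits = []
    for _, d in maps:
        if d not in digits:
            digits.append(d)
    if len(participants) < 2 or len(digits) < 2:
        raise ValueError("need at least 2 participants and 2 digits")
    rows = []
    labels = []
    for d in digits:
        for p in participants:
            if (p, d) not in maps:
                raise ValueError(f"missing map for participant {p}, digit {d}")
            m = _as_bool(maps[(p, d)])
            if not m.any():
                raise ValueError(f"empty map for participant {p}, digit {d}")
            rows.append(m)
            labels.append((p, d))
    M = np.array(rows, dtype=float)
    sizes = M.sum(axis=1)
    inter = M @ M.T
    mat = 2.0 * inter / (sizes[:, None] + sizes[None, :])
    return DiceMatrix(matrix=mat, row_labels=labels,
                      n_participants=len(participants), n_digits=len(digits))


def _mdr_from_blocks(m4: np.ndarray) -> float:
    """MDR from the matrix reshaped to (digit, participant, digit, participant).

    Intradigit and interdigit block means use cross-participant entries
    only; same-participant self-pairs (Dice = 1 by definition on the
    diagonal) are excluded.
    """
    n_d, P = m4.shape[0], m4.shape[1]
    off_p = ~np.eye(P, dtype=bool)
    intra = np.mean([m4[a, :, a, :][off_p].mean() for a in range(n_d)])
    inter_vals = [m4[a, :, b, :][off_p].mean()
                  for a in range(n_d) for b in range(n_d) if a != b]
    inter = float(np.mean(inter_vals))
    if inter == 0.0:
        logger.warning("interdigit overlap is zero; MDR is infinite")
        return float("inf")
    return float(intra / inter)


def _to_block_form(dm: DiceMatrix) -> np.ndarray:
    n_d, P = dm.n_digits, dm.n_participants
    return dm.matrix.reshape(n_d, P, n_d, P)


def mdr(dm: DiceMatrix) -> float:
    """Map dominance ratio: mean intradigit / mean interdigit Dice."""
    return _mdr_from_blocks(_to_block_form(dm))


def mdr_permutation_test(dm: DiceMatrix, n_permutations: int = 5000,
                         seed: int = 0) -> MDRResult:
    """Permutation test of the MDR against within-participant label shuffles.

    Each null sample independently permutes the digit labels within every
    participant and recomputes the MDR; the p-value uses the +1 correction
    p = (1 + #{null >= observed}) / (1 + n_permutations), so it is never
    exactly zero.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    m4 = _to_block_form(dm)
    n_d, P = dm.n_digits, dm.n_participants
    observed = _mdr_from_blocks(m4)
    rng = np.random.default_rng(seed)
    p_idx = np.arange(P)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perms = np.stack([rng.permutation(n_d) for _ in range(P)])  # (P, n_d)
        A = perms.T  # A[a, p] = permuted digit shown at slot a for participant p
        m4p = m4[A[:, :, None, None], p_idx[None, :, None, None],
                 A[None, None, :, :], p_idx[None, None, None, :]]
        null[i] = _mdr_from_blocks(m4p)
    p_value = (1.0 + np.sum(null >= observed)) / (1.0 + n_permutations)
    return MDRResult(mdr=observed, n_permutations=n_permutations,
                     p_value=float(p_value), permuted_mdrs=null)


# ---------------------------------------------------------------------------
# pRF characteristic statistics

def suppression_index(params: PRFParameters) -> float:
    """Ratio of inhibitory to excitatory Gaussian volume of a DoG pRF."""
    if params.model != DOG:
        raise ValueError("suppression index is defined for DoG pRFs only")
    if params.beta_e == 0:
        raise ValueError("suppression index undefined for beta_e = 0")
    num = params.beta_i * params.sigma_x_inhibitory * params.sigma_y_inhibitory
    den = params.beta_e * params.sigma_x * params.sigma_y
    return float(num / den)


def relative_volume(voxel_digit_labels: Sequence[str],
                    label_order: Sequence[str] = DIGIT_LABELS) -> dict[str, float]:
    """Fraction of labeled voxels occupied by each digit (sums to 1)."""
    labels = list(voxel_digit_labels)
    if not labels:
        raise ValueError("no labeled voxels")
    n = len(labels)
    return {lab: labels.count(lab) / n for lab in label_order}


def peak_distances(fits: Sequence[VoxelFitResult],
                   anat: Sequence[Sequence[float]],
                   labels: Sequence[str],
                   label_order: Sequence[str] = DIGIT_LABELS) -> dict[str, float]:
    """Normalized 3D distances from the D1 peak voxel to each digit's peak.

    The peak voxel of a digit is the voxel with the highest free energy;
    distances are Euclidean in anatomical mm and normalized by the
    D1 -> Palm distance, so the last digit maps to 1.
    """
    anat = np.asarray(anat, dtype=float)
    if not (len(fits) == len(anat) == len(labels)):
        raise ValueError("fits, anat and labels must align")
    peaks = {}
    for lab in label_order:
        idx = [i for i, l in enumerate(labels) if l == lab]
        if not idx:
            raise ValueError(f"no voxels for digit {lab}")
        best = max(idx, key=lambda i: fits[i].free_energy)
        peaks[lab] = anat[best]
    origin = peaks[label_order[0]]
    ref = float(np.linalg.norm(peaks[label_order[-1]] - origin))
    if ref == 0:
        raise ValueError("zero D1 -> Palm distance; cannot normalize")
    return {lab: float(np.linalg.norm(peaks[lab] - origin)) / ref
            for lab in label_order[1:]}


def coverage_map(fits: Sequence[VoxelFitResult], space: HandSpace,
                 roi: str | None = None) -> CoverageMap:
    """Group-average normalized sum of pRF profiles over an ROI's voxels.

    Per participant, profiles are summed over voxels (negative DoG
    surrounds floored at zero — a display convention; the suppression
    index keeps the signed parameters) and scaled to a maximum of 1; the
    per-participant maps are then averaged and rescaled to [0, 1].
    """
    selected = [f for f in fits if roi is None or f.roi == roi]
    if not selected:
        raise ValueError(f"no voxels in ROI {roi!r}")
    by_participant: dict[int | None, list[VoxelFitResult]] = {}
    for f in selected:
        by_participant.setdefault(f.participant, []).append(f)
    maps = []
    for group in by_participant.values():
        total = np.zeros((space.grid_resolution, space.grid_resolution))
        for f in group:
            total += prf_profile(f.params, space)
        total = np.clip(total, 0.0, None)
        peak = total.max()
        if peak > 0:
            total = total / peak
        maps.append(total)
    grid = np.mean(maps, axis=0)
    peak = grid.max()
    if peak > 0:
        grid = grid / peak
    return CoverageMap(grid=grid, roi=roi, n_voxels=len(selected))


# ---------------------------------------------------------------------------
# correlations and bootstrap tests

def width_volume_correlation(widths: Sequence[float], volumes: Sequence[float],
                             n_boot: int = 5000, seed: int = 0,
                             ci: float = 0.95) -> dict[str, float]:
    """Pearson correlation between pRF widths and relative volumes.

    Returns r, the two-sided p-value, and a seeded percentile bootstrap
    confidence interval over paired resamples.
    """
    w = np.asarray(widths, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if len(w) != len(v) or len(w) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(w) == 0 or np.std(v) == 0:
        raise ValueError("zero variance in widths or volumes")
    r, p = sps.pearsonr(w, v)
    rng = np.random.default_rng(seed)
    n = len(w)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.std(w[idx]) == 0 or np.std(v[idx]) == 0:
            boots[i] = np.nan
            continue
        boots[i] = np.corrcoef(w[idx], v[idx])[0, 1]
    boots = boots[np.isfinite(boots)]
    alpha = 1.0 - ci
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return {"r": float(r), "p": float(p), "ci_low": float(lo),
            "ci_high": float(hi), "n_boot": int(n_boot)}


def paired_bootstrap_test(a: Sequence[float], b: Sequence[float],
                          n_boot: int = 5000, seed: int = 0) -> dict[str, float]:
    """Paired t-test with a wild-bootstrap-over-participants null.

    The paired differences are centred to zero mean to form the null; wild
    bootstrap resamples (Rademacher sign weights per participant, which
    keep honest small-sample calibration where naive resampling of nine
    subjects is markedly conservative) give a null t distribution, and the
    two-sided p-value is the +1-corrected fraction of null |t| values at
    least as large as the observed |t|.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need paired samples of equal length >= 3")
    d = a - b
    sd = d.std(ddof=1)
    n = len(d)
    if sd == 0:
        if d.mean() == 0:
            return {"t": 0.0, "p": 1.0, "n_boot": int(n_boot)}
        raise ValueError("all paired differences identical; t undefined")
    t_obs = d.mean() / (sd / np.sqrt(n))
    rng = np.random.default_rng(seed)
    d0 = d - d.mean()
    signs = rng.choice([-1.0, 1.0], size=(n_boot, n))
    samples = d0[None, :] * signs
    means = samples.mean(axis=1)
    sds = samples.std(axis=1, ddof=1)
    valid = sds > 0
    t_null = means[valid] / (sds[valid] / np.sqrt(n))
    p = (1.0 + np.sum(np.abs(t_null) >= abs(t_obs))) / (1.0 + len(t_null))
    return {"t": float(t_obs), "p": float(p), "n_boot": int(n_boot)}
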