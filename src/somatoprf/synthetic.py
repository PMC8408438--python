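"""Synthetic phase-encoded BOLD data with known ground-truth pRFs.

The generator emulates the study conditions this package targets: TR = 2 s,
8 s of stimulation per location, 8 cycles per run, 6 between-digit
locations (D1..D5, Palm) or 3 within-digit locations (P1, P2, Palm),
forward and backward run directions, and a 1-mm voxel strip along which
digit identity varies monotonically (mimicking the D1 -> Palm progression
along the postcentral gyrus).  Noise is i.i.d. Gaussian per TR plus a
linear low-frequency drift; an AR(1) option is available.

Every quantity downstream of acquisition is therefore verifiable by
parameter recovery: the ground truth for every voxel is recorded in the
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hemodynamics import DoubleGammaHRF, HemodynamicModel
from .prf_model import DOG, GAUSSIAN, PRFParameters, predict_bold
from .space import (BETWEEN_DIGIT, FORWARD, WITHIN_DIGIT, HandSpace,
                    StimulusDesign, build_design)

__all__ = [
    "GroundTruthVoxel",
    "SyntheticDataset",
    "LayoutBlock",
    "default_layout",
    "default_designs",
    "simulate_voxel",
    "simulate_dataset",
    "simulate_participant_ensemble",
]

ROI_LABELS = ("BA3a", "BA3b", "BA1", "BA2")


@dataclass(frozen=True)
class GroundTruthVoxel:
    """Simulation ground truth for one voxel."""

    voxel_id: int
    anat_xyz: tuple[float, float, float]  # mm, synthetic 3D grid
    roi_label: str
    true_params: PRFParameters
    noise_sd: float
    drift_amplitude: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticDataset:
    """Voxel x time BOLD matrix plus the designs and truth that produced it."""

    bold: np.ndarray
    designs: list[StimulusDesign]
    truth: list[GroundTruthVoxel]
    seed: int
    tr: float

    def __post_init__(self) -> None:
        n_time = sum(d.n_timebins for d in self.designs)
        if self.bold.shape[1] != n_time:
            raise ValueError("bold time length does not match concatenated designs")

    @property
    def n_voxels(self) -> int:
        return self.bold.shape[0]

    @property
    def space(self) -> HandSpace:
        return self.designs[0].space


def _drift(n: int, amplitude: float) -> np.ndarray:
    # linear low-frequency trend spanning [-amp/2, +amp/2] over the run
    return amplitude * np.linspace(-0.5, 0.5, n)


def simulate_voxel(
    params: PRFParameters,
    design: StimulusDesign | Sequence[StimulusDesign],
    space: HandSpace,
    hemodynamics: HemodynamicModel | None = None,
    noise_sd: float = 0.0,
    drift_amplitude: float = 0.0,
    seed: int = 0,
    ar1: float = 0.0,
) -> np.ndarray:
    """Simulate one voxel's BOLD series for one run (or concatenated runs).

    The neuronal drive is the aperture-mean of the pRF profile; the series
    is the hemodynamic response to that drive plus baseline, a linear drift
    per run, and Gaussian noise (AR(1) when ``ar1`` > 0).  Noiseless and
    driftless when both amplitudes are zero.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    hemodynamics = hemodynamics or DoubleGammaHRF()
    designs = [design] if isinstance(design, StimulusDesign) else list(design)
    y = predict_bold(params, designs, space, hemodynamics)
    offset = 0
    for d in designs:
        y[offset:offset + d.n_timebins] += _drift(d.n_timebins, drift_amplitude)
        offset += d.n_timebins
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eps = rng.normal(0.0, noise_sd, size=len(y))
        if ar1 > 0:
            for t in range(1, len(eps)):
                eps[t] += ar1 * eps[t - 1]
            eps *= np.sqrt(1.0 - ar1 ** 2)
        y = y + eps
    return y


@dataclass(frozen=True)
class LayoutBlock:
    """One block of voxels sharing a digit segment and ROI.

    Widths are sampled per voxel from log-normal distributions around the
    block means; centres sit near the segment centre with Gaussian jitter
    (clipped so a voxel's true digit never changes).
    """

    digit_index: int
    roi: str = "BA3b"
    n_voxels: int = 20
    sigma_x_mean: float = 2.5
    sigma_y_mean: float = 4.0
    sigma_log_sd: float = 0.25
    center_jitter_sd: float = 0.5
    y_center: float = 0.0
    y_jitter_sd: float = 1.5
    model: str = GAUSSIAN
    beta_e: float = 1.0
    beta_i_ratio: float = 0.0   # beta_i = ratio * beta_e (DoG blocks)
    sigma_d_mean: float = 0.0


def default_layout(space: HandSpace, n_per_digit: int = 20,
                   model: str = GAUSSIAN, beta_i_ratio: float = 0.0,
                   sigma_d_mean: float = 0.0) -> list[LayoutBlock]:
    """One block per digit segment, ROIs cycled across blocks."""
    blocks = []
    for k in range(space.n_digit_segments):
        blocks.append(LayoutBlock(
            digit_index=k,
            roi=ROI_LABELS[k % len(ROI_LABELS)],
            n_voxels=n_per_digit,
            model=model,
            beta_i_ratio=beta_i_ratio,
            sigma_d_mean=sigma_d_mean,
        ))
    return blocks


def default_designs(space: HandSpace,
                    dimensions: Sequence[str] = (BETWEEN_DIGIT, WITHIN_DIGIT),
                    ) -> list[StimulusDesign]:
    """The full session: forward and backward runs of each dimension.

    Both dimensions are needed to identify a 2D pRF: a between-digit run
    constrains (x0, sigma_x) only — its apertures span the full y-extent,
    so the y-profile enters as a pure gain — and vice versa.
    """
    designs = []
    for dim in dimensions:
        f = build_design(space, dim, FORWARD)
        designs += [f, f.reversed()]
    return designs


def _sample_truth(layout: Sequence[LayoutBlock], space: HandSpace,
                  rng: np.random.Generator) -> list[PRFParameters]:
    from .prf_model import SIGMA_MIN, SIGMA_MAX

    params = []
    for block in layout:
        half = 0.5 * space.digit_width
        cx = space.segment_center(block.digit_index)
        for _ in range(block.n_voxels):
            x0 = cx + rng.normal(0.0, block.center_jitter_sd)
            x0 = float(np.clip(x0, cx - 0.75 * half, cx + 0.75 * half))
            y0 = block.y_center + rng.normal(0.0, block.y_jitter_sd)
            y0 = float(np.clip(y0, space.y_min + 1.0, space.y_max - 1.0))
            sx = float(np.clip(block.sigma_x_mean * rng.lognormal(0.0, block.sigma_log_sd),
                               SIGMA_MIN, SIGMA_MAX))
            sy = float(np.clip(block.sigma_y_mean * rng.lognormal(0.0, block.sigma_log_sd),
                               SIGMA_MIN, SIGMA_MAX))
            sd = 0.0
            bi = 0.0
            if block.model == DOG:
                sd = float(np.clip(block.sigma_d_mean * rng.lognormal(0.0, 0.2), 0.0, 24.0))
                bi = block.beta_i_ratio * block.beta_e
            params.append(PRFParameters(
                model=block.model, x0=x0, y0=y0, sigma_x=sx, sigma_y=sy,
                sigma_d=sd, beta_e=block.beta_e, beta_i=bi, baseline=0.0,
            ))
    return params


def simulate_dataset(
    layout: Sequence[LayoutBlock] | None = None,
    designs: Sequence[StimulusDesign] | None = None,
    space: HandSpace | None = None,
    noise_sd: float | None = None,
    snr: float | None = None,
    drift_amplitude: float = 0.0,
    seed: int = 0,
    hemodynamics: HemodynamicModel | None = None,
) -> SyntheticDataset:
    """Simulate a multi-voxel phase-encoded dataset with recorded truth.

    Voxels are laid out along a synthetic 1-mm strip so that digit identity
    is monotone along the anatomical x-axis.  Noise level is set either
    directly (``noise_sd``) or via a per-voxel temporal SNR
    (``snr`` = std(signal)/noise_sd); both zero/None means noiseless.
    """
    space = space or HandSpace()
    if designs is None:
        designs = default_designs(space)
    designs = list(designs)
    if not designs:
        raise ValueError("empty design list")
    layout = list(layout) if layout is not None else default_layout(space)
    if sum(b.n_voxels for b in layout) < 1:
        raise ValueError("layout must assign at least one voxel")
    hemodynamics = hemodynamics or DoubleGammaHRF()

    root = np.random.SeedSequence(seed)
    truth_rng = np.random.default_rng(root.spawn(1)[0])
    all_params = _sample_truth(layout, space, truth_rng)
    rois = [b.roi for b in layout for _ in range(b.n_voxels)]

    n_vox = len(all_params)
    n_time = sum(d.n_timebins for d in designs)
    bold = np.empty((n_vox, n_time))
    truth: list[GroundTruthVoxel] = []
    noise_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(n_vox + 1)[1:]]
    for i, params in enumerate(all_params):
        clean = simulate_voxel(params, designs, space, hemodynamics)
        if snr is not None and snr > 0:
            sd_sig = float(np.std(clean))
            nsd = sd_sig / snr if sd_sig > 0 else 0.0
        else:
            nsd = float(noise_sd or 0.0)
        bold[i] = simulate_voxel(params, designs, space, hemodynamics,
                                 noise_sd=nsd, drift_amplitude=drift_amplitude,
                                 seed=noise_seeds[i])
        truth.append(GroundTruthVoxel(
            voxel_id=i,
            anat_xyz=(float(i), 0.0, 0.0),  # 1-mm strip, digit monotone in x
            roi_label=rois[i],
            true_params=params,
            noise_sd=nsd,
            drift_amplitude=drift_amplitude,
        ))
    return SyntheticDataset(bold=bold, designs=designs, truth=truth,
                            seed=seed, tr=designs[0].tr)


def simulate_participant_ensemble(
    n_participants: int = 9,
    center_jitter_sd: float = 0.0,
    seed: int = 0,
    n_digits: int = 6,
    voxels_per_digit: int = 20,
) -> dict[tuple[int, str], np.ndarray]:
    """Per-(participant, digit) binary voxel sets on a shared anatomical strip.

    Each participant's digit territories partition a strip of
    ``n_digits * voxels_per_digit`` voxels; jitter displaces digit-territory
    centres between participants (each voxel goes to the nearest centre).
    With zero jitter all participants share identical, disjoint territories.
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    if center_jitter_sd < 0:
        raise ValueError("center_jitter_sd must be >= 0")
    labels = [f"D{i + 1}" for i in range(n_digits - 1)] + ["Palm"] \
        if n_digits == 6 else [f"L{i + 1}" for i in range(n_digits)]
    n_vox = n_digits * voxels_per_digit
    base_centers = (np.arange(n_digits) + 0.5) * voxels_per_digit
    pos = np.arange(n_vox) + 0.5
    rng = np.random.default_rng(seed)
    maps: dict[tuple[int, str], np.ndarray] = {}
    for p in range(n_participants):
        centers = base_centers + rng.normal(0.0, center_jitter_sd, size=n_digits)
        assign = np.argmin(np.abs(pos[:, None] - centers[None, :]), axis=1)
        for d in range(n_digits):
            mask = assign == d
            if not mask.any():
                # keep every map nonempty: claim the voxel nearest the centre
                mask = np.zeros(n_vox, dtype=bool)
                mask[int(np.clip(round(centers[d] - 0.5), 0, n_vox - 1))] = True
            maps[(p, labels[d])] = mask
    return maps
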