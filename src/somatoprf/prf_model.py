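"""Parametric pRF profiles and the shared BOLD forward model.

A population receptive field (pRF) summarizes, per voxel, which part of the
hand space drives the voxel's aggregate response.  Two profiles are
supported:

* Gaussian ellipse — an axis-aligned excitatory 2D Gaussian with centre
  (x0, y0), widths (sigma_x, sigma_y) and amplitude beta_e.
* DoG (difference-of-Gaussians) ellipse — the excitatory Gaussian minus a
  broader inhibitory Gaussian with widths (sigma_x + sigma_d,
  sigma_y + sigma_d) and amplitude beta_i, giving a centre-surround profile
  that may be negative in the surround.

The neuronal drive at time-bin t integrates the profile over the active
aperture (mean over active grid points), so between- and within-digit
designs yield comparable amplitudes.  The same drive definition is used by
the synthetic generator and the estimator, guaranteeing simulate/fit
consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hemodynamics import HemodynamicModel
from .space import HandSpace, StimulusDesign

__all__ = [
    "PRFParameters",
    "GAUSSIAN",
    "DOG",
    "SIGMA_MIN",
    "SIGMA_MAX",
    "SIGMA_D_MAX",
    "prf_profile",
    "neural_drive",
    "predict_bold",
]

GAUSSIAN = "gaussian_ellipse"
DOG = "dog_ellipse"

#: Estimation bounds on widths (hand-space units).
SIGMA_MIN = 0.5
SIGMA_MAX = 24.0
SIGMA_D_MAX = 24.0


@dataclass(frozen=True)
class PRFParameters:
    """Per-voxel pRF parameter record (Gaussian or DoG ellipse)."""

    model: str = GAUSSIAN
    x0: float = 0.0
    y0: float = 0.0
    sigma_x: float = 2.0
    sigma_y: float = 2.0
    sigma_d: float = 0.0   # inhibitory-minus-excitatory width difference (DoG)
    beta_e: float = 1.0    # excitatory amplitude
    beta_i: float = 0.0    # inhibitory amplitude (DoG)
    baseline: float = 0.0

    def validate(self, space: HandSpace) -> None:
        if self.model not in (GAUSSIAN, DOG):
            raise ValueError(f"unknown pRF model {self.model!r}")
        if not (space.x_min <= self.x0 <= space.x_max):
            raise ValueError(f"x0={self.x0} outside hand space")
        if not (space.y_min <= self.y0 <= space.y_max):
            raise ValueError(f"y0={self.y0} outside hand space")
        for name, s in (("sigma_x", self.sigma_x), ("sigma_y", self.sigma_y)):
            if not (SIGMA_MIN <= s <= SIGMA_MAX):
                raise ValueError(f"{name}={s} outside [{SIGMA_MIN}, {SIGMA_MAX}]")
        if not (0.0 <= self.sigma_d <= SIGMA_D_MAX):
            raise ValueError(f"sigma_d={self.sigma_d} outside [0, {SIGMA_D_MAX}]")
        if self.beta_e < 0 or self.beta_i < 0:
            raise ValueError("amplitudes must be non-negative")

    @property
    def sigma_x_inhibitory(self) -> float:
        return self.sigma_x + self.sigma_d

    @property
    def sigma_y_inhibitory(self) -> float:
        return self.sigma_y + self.sigma_d


def prf_profile(params: PRFParameters, space: HandSpace) -> np.ndarray:
    """Evaluate the pRF profile on the hand-space grid, shape (res, res)."""
    params.validate(space)
    X, Y = space.grid
    exc = params.beta_e * np.exp(
        -((X - params.x0) ** 2) / (2.0 * params.sigma_x ** 2)
        - ((Y - params.y0) ** 2) / (2.0 * params.sigma_y ** 2)
    )
    if params.model == GAUSSIAN:
        return exc
    sx_i = params.sigma_x_inhibitory
    sy_i = params.sigma_y_inhibitory
    inh = params.beta_i * np.exp(
        -((X - params.x0) ** 2) / (2.0 * sx_i ** 2)
        - ((Y - params.y0) ** 2) / (2.0 * sy_i ** 2)
    )
    return exc - inh


def _location_drives(profile: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Mean profile value over each location's aperture (normalizes by count)."""
    flat = profile.reshape(-1)
    return np.array([flat[m.reshape(-1)].mean() for m in masks])


def neural_drive(params: PRFParameters, design: StimulusDesign,
                 space: HandSpace) -> np.ndarray:
    """Neuronal drive z(t): aperture-mean of the pRF profile per time-bin."""
    if design.space != space:
        raise ValueError("design was built on a different hand space")
    profile = prf_profile(params, space)
    drives = _location_drives(profile, design.masks)
    return drives[design.location_sequence]


def predict_bold(params: PRFParameters, design: StimulusDesign | Sequence[StimulusDesign],
                 space: HandSpace, hemodynamics: HemodynamicModel) -> np.ndarray:
    """Noiseless BOLD prediction: hemodynamics applied to z(t), plus baseline.

    A sequence of designs is treated as concatenated runs; the hemodynamic
    response does not bleed across run boundaries.
    """
    designs = [design] if isinstance(design, StimulusDesign) else list(design)
    parts = []
    for d in designs:
        z = neural_drive(params, d, space)
        parts.append(hemodynamics.evaluate(z, d.tr))
    return np.concatenate(parts) + params.baseline
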