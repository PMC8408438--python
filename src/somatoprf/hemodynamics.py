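"""Hemodynamic forward models mapping neuronal drive to BOLD signal.

Two interchangeable implementations share one contract
(:class:`HemodynamicModel`): a canonical double-gamma HRF convolution
(linear, fast — the default for both simulation and fitting) and a
Balloon/Windkessel ODE model (nonlinear, biophysical — used for fidelity
checks).  Both map an all-zero drive to an all-zero (baseline) output.

Neuronal drive is piecewise-constant at TR resolution.  The convolution
path exploits this: the kernel is pre-convolved with a TR-wide box on a
fine time grid and sampled at TR, which makes TR-resolution convolution
exact for block drives.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = [
    "HemodynamicModel",
    "DoubleGammaHRF",
    "BalloonModel",
    "gamma_kernel",
    "double_gamma_kernel",
]

#: Internal fine-grid step (s) for kernel construction and ODE integration.
FINE_DT = 0.01
#: Kernel support (s); the double-gamma HRF is negligible beyond this.
KERNEL_LENGTH = 32.0


def gamma_kernel(dt: float = FINE_DT, shape: float = 6.0, scale: float = 1.0,
                 length: float = KERNEL_LENGTH) -> np.ndarray:
    """Single-gamma impulse response sampled at dt, unit integral.

    With the default shape 6 / scale 1 the kernel peaks at 5 s, a standard
    choice for hemodynamic lag.
    """
    t = np.arange(0.0, length, dt)
    h = gamma_dist.pdf(t, shape, scale=scale)
    return h / (h.sum() * dt)


def double_gamma_kernel(dt: float = FINE_DT, peak_shape: float = 6.0,
                        undershoot_shape: float = 16.0,
                        undershoot_ratio: float = 1.0 / 6.0,
                        length: float = KERNEL_LENGTH) -> np.ndarray:
    """Canonical double-gamma HRF (peak ~5 s, undershoot ~15 s), unit net integral."""
    t = np.arange(0.0, length, dt)
    h = gamma_dist.pdf(t, peak_shape) - undershoot_ratio * gamma_dist.pdf(t, undershoot_shape)
    return h / (h.sum() * dt)


def _block_taps(kernel: np.ndarray, tr: float, dt: float) -> np.ndarray:
    """Response of the kernel to a TR-wide unit box, sampled at TR endpoints.

    Convolving a TR-resolution drive with these taps reproduces the
    fine-grid convolution of the held (piecewise-constant) drive exactly.
    """
    n_box = int(round(tr / dt))
    box = np.ones(n_box)
    resp = np.convolve(box, kernel) * dt
    n_taps = int(np.ceil(len(resp) / n_box))
    idx = (np.arange(1, n_taps + 1) * n_box - 1).clip(max=len(resp) - 1)
    return resp[idx]


class HemodynamicModel:
    """Contract: ``evaluate(z, tr)`` maps a neuronal drive series to BOLD."""

    def evaluate(self, z: np.ndarray, tr: float) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class DoubleGammaHRF(HemodynamicModel):
    """Linear convolution with the canonical double-gamma HRF."""

    peak_shape: float = 6.0
    undershoot_shape: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0

    def kernel(self, dt: float = FINE_DT) -> np.ndarray:
        return double_gamma_kernel(dt, self.peak_shape, self.undershoot_shape,
                                   self.undershoot_ratio)

    def taps(self, tr: float) -> np.ndarray:
        return _cached_taps(self.peak_shape, self.undershoot_shape,
                            self.undershoot_ratio, tr)

    def evaluate(self, z: np.ndarray, tr: float) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite neuronal drive")
        return np.convolve(z, self.taps(tr))[: len(z)]


@lru_cache(maxsize=32)
def _cached_taps(peak_shape: float, undershoot_shape: float,
                 undershoot_ratio: float, tr: float) -> np.ndarray:
    k = double_gamma_kernel(FINE_DT, peak_shape, undershoot_shape, undershoot_ratio)
    return _block_taps(k, tr, FINE_DT)


@lru_cache(maxsize=32)
def _cached_gamma_taps(shape: float, scale: float, tr: float) -> np.ndarray:
    return _block_taps(gamma_kernel(FINE_DT, shape, scale), tr, FINE_DT)


@dataclass(frozen=True)
class BalloonModel(HemodynamicModel):
    """Balloon/Windkessel hemodynamics integrated at sub-TR steps.

    States: vasodilatory signal s, inflow f, blood volume v, deoxyhemoglobin
    content q.  The BOLD output combines (1-q), (1-q/v) and (1-v) with
    field-strength-dependent weights.  Defaults are the standard published
    neurovascular-coupling values; ``e0`` (resting oxygen extraction) and
    ``v0`` (resting venous volume fraction) are exposed because they carry
    the field-strength dependence.
    """

    kappa: float = 0.64   # signal decay rate (1/s)
    gamma: float = 0.32   # autoregulatory feedback rate (1/s)
    tau: float = 2.0      # venous transit time (s)
    alpha: float = 0.32   # vessel stiffness (Grubb) exponent
    e0: float = 0.4       # resting oxygen extraction fraction
    v0: float = 0.02      # resting venous blood volume fraction
    epsilon: float = 0.5  # neuronal efficacy (drive gain)
    dt: float = FINE_DT   # integration step (s)

    def evaluate(self, z: np.ndarray, tr: float) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite neuronal drive")
        n_sub = int(round(tr / self.dt))
        s, f, v, q = 0.0, 1.0, 1.0, 1.0
        k1 = 7.0 * self.e0
        k2 = 2.0
        k3 = 2.0 * self.e0 - 0.2
        out = np.empty(len(z))
        inv_alpha = 1.0 / self.alpha
        for t in range(len(z)):
            drive = self.epsilon * z[t]
            for _ in range(n_sub):
                fv = v ** inv_alpha
                ff = (1.0 - (1.0 - self.e0) ** (1.0 / f)) / self.e0
                ds = drive - self.kappa * s - self.gamma * (f - 1.0)
                df = s
                dv = (f - fv) / self.tau
                dq = (f * ff - fv * q / v) / self.tau
                s += self.dt * ds
                f += self.dt * df
                v += self.dt * dv
                q += self.dt * dq
            out[t] = self.v0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
        return out
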