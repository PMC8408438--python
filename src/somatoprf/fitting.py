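"""Voxel-wise pRF estimation: grid search, MAP optimization, Laplace evidence.

Each voxel's BOLD series (one run or concatenated forward/backward runs,
with run-specific baseline and linear drift) is fit with a Gaussian-ellipse
or DoG-ellipse pRF under Gaussian priors: the pRF centre prior is centred
on the origin with a standard deviation of half the space range (12 units),
and width priors live on a log scale within the bounds [0.5, 24]
(sigma_d in [0, 24]).  Bounds are enforced by smooth reparameterization
(tanh / logistic maps), so the optimum is interior and the Hessian there is
meaningful.

Model evidence is approximated by the Laplace method at the MAP estimate:

    F = log p(y | theta_hat) + log p(theta_hat) + (d/2) log 2*pi
        - (1/2) log det H,

with H the Hessian of the negative log posterior (in the unconstrained
latent coordinates, change-of-variables terms included).  F differences
behave like log Bayes factors: |F1 - F2| < 3 is treated as indeterminate.
The posterior probability of a pRF model against an intercept+drift-only
null is sigmoid(F_model - F_null).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .hemodynamics import DoubleGammaHRF, HemodynamicModel
from .prf_model import (DOG, GAUSSIAN, SIGMA_D_MAX, SIGMA_MAX, SIGMA_MIN,
                        PRFParameters)
from .space import HandSpace, StimulusDesign

__all__ = [
    "PriorSpec",
    "VoxelFitResult",
    "ModelComparison",
    "grid_search_init",
    "fit_voxel",
    "fit_voxels",
    "compare_models",
    "EVIDENCE_BAND",
]

logger = logging.getLogger(__name__)

#: |F_gaussian - F_dog| below this is indeterminate (log-evidence units).
EVIDENCE_BAND = 3.0

NULL = "null"
_LN2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian priors on the pRF parameters (natural scale).

    ``center_sd`` is half the default space range.  Width priors are
    log-normal around a typical segment width; amplitude priors are
    log-normal and weak.  ``lns_*`` parameterize the prior on the log noise
    standard deviation.
    """

    center_sd: float = 12.0
    log_width_mean: float = float(np.log(4.0))
    log_width_sd: float = 1.0
    sigma_d_sd: float = 6.0          # half-normal scale on the width difference
    log_beta_e_mean: float = 0.0
    log_beta_e_sd: float = 2.0
    log_beta_i_mean: float = -1.5
    log_beta_i_sd: float = 2.0
    baseline_sd: float = 10.0
    drift_sd: float = 10.0
    lns_mean: float = 0.0
    lns_sd: float = 2.0


@dataclass
class VoxelFitResult:
    """MAP fit of one model to one voxel."""

    voxel_id: int
    params: PRFParameters
    free_energy: float
    posterior_model_prob: float
    r_fit: float
    converged: bool
    model: str = GAUSSIAN
    free_energy_null: float = float("nan")
    run_baselines: tuple[float, ...] = ()
    run_drifts: tuple[float, ...] = ()
    noise_sd: float = float("nan")
    roi: str | None = None
    participant: int | None = None


@dataclass(frozen=True)
class ModelComparison:
    """Gaussian-vs-DoG evidence comparison for one voxel."""

    voxel_id: int
    delta_f: float  # F_gaussian - F_dog
    verdict: str    # gaussian | dog | indeterminate


def _normal_logpdf(x: float, mean: float, sd: float) -> float:
    return -0.5 * _LN2PI - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


class _ForwardProblem:
    """Precomputed design structure for fast repeated prediction."""

    def __init__(self, designs: Sequence[StimulusDesign], space: HandSpace,
                 hemodynamics: HemodynamicModel):
        self.designs = list(designs)
        self.space = space
        self.hemo = hemodynamics
        self.X, self.Y = space.grid
        self.run_lengths = [d.n_timebins for d in self.designs]
        self.n_time = sum(self.run_lengths)
        # per design: aperture-mean operator (n_locations x n_gridpoints)
        self.mean_ops = []
        self.loc_seqs = []
        for d in self.designs:
            if d.space != space:
                raise ValueError("design was built on a different hand space")
            masks = d.masks.reshape(d.masks.shape[0], -1).astype(float)
            self.mean_ops.append(masks / masks.sum(axis=1, keepdims=True))
            self.loc_seqs.append(d.location_sequence)
        self.drift_regs = [np.linspace(-0.5, 0.5, n) for n in self.run_lengths]

    def profile(self, x0, y0, sx, sy, sd, be, bi, model) -> np.ndarray:
        p = np.exp(-((self.X - x0) ** 2) / (2.0 * sx ** 2)
                   - ((self.Y - y0) ** 2) / (2.0 * sy ** 2))
        if model == GAUSSIAN or bi == 0.0:
            return be * p
        sxi, syi = sx + sd, sy + sd
        q = np.exp(-((self.X - x0) ** 2) / (2.0 * sxi ** 2)
                   - ((self.Y - y0) ** 2) / (2.0 * syi ** 2))
        return be * p - bi * q

    def response(self, x0, y0, sx, sy, sd, be, bi, model) -> np.ndarray:
        """Concatenated hemodynamic response (no baseline/drift)."""
        flat = self.profile(x0, y0, sx, sy, sd, be, bi, model).reshape(-1)
        parts = []
        for op, seq, d in zip(self.mean_ops, self.loc_seqs, self.designs):
            z = (op @ flat)[seq]
            parts.append(self.hemo.evaluate(z, d.tr))
        return np.concatenate(parts)

    def add_trends(self, y: np.ndarray, baselines, drifts) -> np.ndarray:
        out = y.copy()
        off = 0
        for n, reg, b, m in zip(self.run_lengths, self.drift_regs, baselines, drifts):
            out[off:off + n] += b + m * reg
            off += n
        return out


# ---------------------------------------------------------------------------
# latent <-> natural parameter maps

def _center_fwd(u: float, half: float) -> float:
    return half * np.tanh(u)


def _center_inv(x: float, half: float) -> float:
    return float(np.arctanh(np.clip(x / half, -0.999, 0.999)))


def _width_fwd(u: float) -> float:
    return SIGMA_MIN + (SIGMA_MAX - SIGMA_MIN) * expit(u)


def _width_inv(s: float) -> float:
    frac = np.clip((s - SIGMA_MIN) / (SIGMA_MAX - SIGMA_MIN), 1e-4, 1 - 1e-4)
    return float(logit(frac))


def _sigd_fwd(u: float) -> float:
    return SIGMA_D_MAX * expit(u)


def _sigd_inv(s: float) -> float:
    return float(logit(np.clip(s / SIGMA_D_MAX, 1e-4, 1 - 1e-4)))


class _ModelSpec:
    """Packs/unpacks the latent vector and evaluates the log prior."""

    def __init__(self, model: str, n_runs: int, space: HandSpace, priors: PriorSpec):
        self.model = model
        self.n_runs = n_runs
        self.priors = priors
        self.half_x = 0.5 * (space.x_max - space.x_min)
        self.half_y = 0.5 * (space.y_max - space.y_min)
        self.mid_x = 0.5 * (space.x_max + space.x_min)
        self.mid_y = 0.5 * (space.y_max + space.y_min)
        if model == NULL:
            self.n_prf = 0
        elif model == GAUSSIAN:
            self.n_prf = 5   # ux, uy, usx, usy, ube
        elif model == DOG:
            self.n_prf = 7   # + usd, ubi
        else:
            raise ValueError(f"unknown model {model!r}")
        self.dim = self.n_prf + 2 * n_runs + 1

    def unpack(self, u: np.ndarray) -> dict:
        p = self.priors
        i = self.n_prf
        out = {
            "baselines": u[i:i + self.n_runs],
            "drifts": u[i + self.n_runs:i + 2 * self.n_runs],
            "lns": u[-1],
        }
        if self.model == NULL:
            return out
        out["x0"] = self.mid_x + _center_fwd(u[0], self.half_x)
        out["y0"] = self.mid_y + _center_fwd(u[1], self.half_y)
        out["sx"] = _width_fwd(u[2])
        out["sy"] = _width_fwd(u[3])
        out["be"] = np.exp(np.clip(u[4], -30.0, 30.0))
        if self.model == DOG:
            out["sd"] = _sigd_fwd(u[5])
            out["bi"] = np.exp(np.clip(u[6], -30.0, 30.0))
        else:
            out["sd"] = 0.0
            out["bi"] = 0.0
        return out

    def pack(self, params: PRFParameters, baselines, drifts, lns: float) -> np.ndarray:
        u = []
        if self.model != NULL:
            u += [_center_inv(params.x0 - self.mid_x, self.half_x),
                  _center_inv(params.y0 - self.mid_y, self.half_y),
                  _width_inv(params.sigma_x),
                  _width_inv(params.sigma_y),
                  float(np.log(max(params.beta_e, 1e-6)))]
            if self.model == DOG:
                u += [_sigd_inv(max(params.sigma_d, 1e-3)),
                      float(np.log(max(params.beta_i, 1e-6)))]
        u += list(baselines) + list(drifts) + [lns]
        return np.array(u, dtype=float)

    def log_prior(self, u: np.ndarray, nat: dict) -> float:
        """Prior density on the natural scale plus change-of-variable terms."""
        p = self.priors
        lp = 0.0
        if self.model != NULL:
            # centres: N(0, center_sd) with tanh Jacobian
            for uu, x, half, mid in ((u[0], nat["x0"], self.half_x, self.mid_x),
                                     (u[1], nat["y0"], self.half_y, self.mid_y)):
                lp += _normal_logpdf(x - mid, 0.0, p.center_sd)
                lp += np.log(half) + np.log(max(1.0 - np.tanh(uu) ** 2, 1e-300))
            # widths: log-normal with logistic Jacobian
            for uu, s in ((u[2], nat["sx"]), (u[3], nat["sy"])):
                lp += _normal_logpdf(np.log(s), p.log_width_mean, p.log_width_sd) - np.log(s)
                e = expit(uu)
                lp += np.log((SIGMA_MAX - SIGMA_MIN) * e * (1.0 - e) + 1e-300)
            # amplitude: log-normal, latent is the log directly
            lp += _normal_logpdf(u[4], p.log_beta_e_mean, p.log_beta_e_sd)
            if self.model == DOG:
                e = expit(u[5])
                lp += _normal_logpdf(nat["sd"], 0.0, p.sigma_d_sd) + np.log(2.0)
                lp += np.log(SIGMA_D_MAX * e * (1.0 - e) + 1e-300)
                lp += _normal_logpdf(u[6], p.log_beta_i_mean, p.log_beta_i_sd)
        for b in nat["baselines"]:
            lp += _normal_logpdf(b, 0.0, p.baseline_sd)
        for m in nat["drifts"]:
            lp += _normal_logpdf(m, 0.0, p.drift_sd)
        lp += _normal_logpdf(nat["lns"], p.lns_mean, p.lns_sd)
        return lp


def _make_objective(problem: _ForwardProblem, spec: _ModelSpec, y: np.ndarray):
    T = len(y)

    def predict(nat: dict) -> np.ndarray:
        if spec.model == NULL:
            base = np.zeros(T)
        else:
            base = problem.response(nat["x0"], nat["y0"], nat["sx"], nat["sy"],
                                    nat["sd"], nat["be"], nat["bi"], spec.model)
        return problem.add_trends(base, nat["baselines"], nat["drifts"])

    def neg_log_post(u: np.ndarray) -> float:
        nat = spec.unpack(u)
        resid = y - predict(nat)
        lns = np.clip(nat["lns"], -20.0, 20.0)
        sigma2 = np.exp(2.0 * lns)
        loglik = -0.5 * T * (_LN2PI + 2.0 * lns) - 0.5 * resid @ resid / sigma2
        val = -(loglik + spec.log_prior(u, nat))
        if not np.isfinite(val):  # overflow far off the posterior mode
            return 1e12
        return float(val)

    return predict, neg_log_post


def _numeric_hessian(f, u: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    d = len(u)
    h = rel_step * (1.0 + np.abs(u))
    H = np.empty((d, d))
    f0 = f(u)
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        e = np.zeros(d); e[i] = h[i]
        fp[i] = f(u + e)
        fm[i] = f(u - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            e_i = np.zeros(d); e_i[i] = h[i]
            e_j = np.zeros(d); e_j[j] = h[j]
            fpp = f(u + e_i + e_j)
            fmm = f(u - e_i - e_j)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fmm) \
                / (2.0 * h[i] * h[j])
    return H


def _laplace_free_energy(neg_log_post, u_hat: np.ndarray) -> float:
    d = len(u_hat)
    H = _numeric_hessian(neg_log_post, u_hat)
    H = 0.5 * (H + H.T)
    eigvals = np.linalg.eigvalsh(H)
    eigvals = np.clip(eigvals, 1e-8, None)
    logdet = float(np.sum(np.log(eigvals)))
    return float(-neg_log_post(u_hat) + 0.5 * d * _LN2PI - 0.5 * logdet)


# ---------------------------------------------------------------------------

def grid_search_init(
    bold: np.ndarray,
    designs: StimulusDesign | Sequence[StimulusDesign],
    space: HandSpace,
    hemodynamics: HemodynamicModel | None = None,
    x0_grid: Sequence[float] | None = None,
    y0_grid: Sequence[float] | None = None,
    sigma_grid: Sequence[float] | None = None,
    full_output: bool = False,
):
    """Coarse grid search over (x0, y0, isotropic sigma) for the fit seed.

    At each node the neuronal response shape is fixed and the amplitude,
    per-run baseline and per-run drift are solved by one least-squares fit;
    the node with minimum residual sum of squares seeds the optimizer.
    Exactly one least-squares solve is performed per node.
    """
    y = np.asarray(bold, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite BOLD series")
    designs = [designs] if isinstance(designs, StimulusDesign) else list(designs)
    hemodynamics = hemodynamics or DoubleGammaHRF()
    problem = _ForwardProblem(designs, space, hemodynamics)
    if x0_grid is None:
        x0_grid = np.linspace(space.x_min + 1.0, space.x_max - 1.0, 11)
    if y0_grid is None:
        y0_grid = np.linspace(space.y_min + 2.0, space.y_max - 2.0, 5)
    if sigma_grid is None:
        sigma_grid = (1.0, 2.0, 4.0, 8.0)

    if np.std(y) == 0:
        info = {"n_solves": 0, "degenerate": True, "rss": float("nan")}
        params = PRFParameters(model=GAUSSIAN, x0=0.0, y0=0.0,
                               sigma_x=SIGMA_MIN, sigma_y=SIGMA_MIN,
                               beta_e=1e-6, baseline=float(y[0]))
        return (params, info) if full_output else params

    n_runs = len(designs)
    trend_cols = []
    off = 0
    for n, reg in zip(problem.run_lengths, problem.drift_regs):
        b = np.zeros(problem.n_time); b[off:off + n] = 1.0
        m = np.zeros(problem.n_time); m[off:off + n] = reg
        trend_cols += [b, m]
        off += n
    trends = np.column_stack(trend_cols)
    # constrained fallback: amplitudes are non-negative, so a node whose
    # unconstrained amplitude comes out negative is scored at beta = 0,
    # i.e. with the trends-only residual
    coef_t, _, _, _ = np.linalg.lstsq(trends, y, rcond=None)
    rss_trends = float(np.sum((y - trends @ coef_t) ** 2))

    best = None
    n_solves = 0
    for sig in sigma_grid:
        for x0 in x0_grid:
            for y0 in y0_grid:
                resp = problem.response(x0, y0, sig, sig, 0.0, 1.0, 0.0, GAUSSIAN)
                A = np.column_stack([resp, trends])
                coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
                n_solves += 1
                if coef[0] < 0:
                    rss = rss_trends
                    coef = np.concatenate([[0.0], coef_t])
                else:
                    rss = float(np.sum((y - A @ coef) ** 2))
                if best is None or rss < best[0]:
                    best = (rss, x0, y0, sig, coef)
    rss, x0, y0, sig, coef = best
    beta = float(max(coef[0], 1e-6))
    baselines = coef[1::2]
    params = PRFParameters(model=GAUSSIAN, x0=float(x0), y0=float(y0),
                           sigma_x=float(sig), sigma_y=float(sig),
                           beta_e=beta, baseline=float(np.mean(baselines)))
    info = {"n_solves": n_solves, "degenerate": False, "rss": rss,
            "baselines": tuple(float(b) for b in baselines),
            "drifts": tuple(float(m) for m in coef[2::2])}
    return (params, info) if full_output else params


def fit_voxel(
    bold: np.ndarray,
    designs: StimulusDesign | Sequence[StimulusDesign],
    space: HandSpace,
    model: str = GAUSSIAN,
    hemodynamics: HemodynamicModel | None = None,
    priors: PriorSpec | None = None,
    voxel_id: int = 0,
    init: PRFParameters | None = None,
    maxiter: int = 400,
    fit_null: bool = True,
) -> VoxelFitResult:
    """MAP fit of one pRF model to one voxel, with Laplace model evidence.

    Returns the fitted parameters, the free-energy approximation to log
    model evidence, and the posterior probability of the model against an
    intercept+drift-only null.  Deterministic: the same input always yields
    the same result.
    """
    y = np.asarray(bold, dtype=float)
    designs = [designs] if isinstance(designs, StimulusDesign) else list(designs)
    n_time = sum(d.n_timebins for d in designs)
    if len(y) != n_time:
        raise ValueError(f"bold length {len(y)} does not match designs ({n_time})")
    hemodynamics = hemodynamics or DoubleGammaHRF()
    priors = priors or PriorSpec()
    problem = _ForwardProblem(designs, space, hemodynamics)
    n_runs = len(designs)

    if init is None:
        init, ginfo = grid_search_init(y, designs, space, hemodynamics, full_output=True)
        init_baselines = ginfo.get("baselines", (float(np.mean(y)),) * n_runs)
        init_drifts = ginfo.get("drifts", (0.0,) * n_runs)
        init_rss = ginfo.get("rss", float(np.var(y)) * len(y))
    else:
        init_baselines = (float(np.mean(y)),) * n_runs
        init_drifts = (0.0,) * n_runs
        init_rss = float(np.var(y)) * len(y)
    inits = [init]
    if model == DOG and init.model != DOG:
        # the centre-surround posterior can be multimodal; start from both a
        # weak-surround and a strong-surround seed and keep the better optimum
        inits = [
            PRFParameters(model=DOG, x0=init.x0, y0=init.y0,
                          sigma_x=init.sigma_x, sigma_y=init.sigma_y,
                          sigma_d=1.0, beta_e=init.beta_e,
                          beta_i=0.1 * init.beta_e, baseline=init.baseline),
            PRFParameters(model=DOG, x0=init.x0, y0=init.y0,
                          sigma_x=init.sigma_x, sigma_y=init.sigma_y,
                          sigma_d=3.0, beta_e=init.beta_e,
                          beta_i=0.6 * init.beta_e, baseline=init.baseline),
        ]

    spec = _ModelSpec(model, n_runs, space, priors)
    predict, neg_log_post = _make_objective(problem, spec, y)
    resid_sd = np.sqrt(max(init_rss, 1e-12) / max(n_time, 1))
    lns0 = float(np.log(max(resid_sd, 1e-6)))

    res = None
    for cand in inits:
        u0 = spec.pack(cand, init_baselines, init_drifts, lns0)
        # stage 1: shape/amplitude/trends with the noise scale held fixed --
        # letting the noise scale collapse first freezes the shape parameters
        # on near-noiseless data
        def fixed_lns(v, _lns=u0[-1]):
            return neg_log_post(np.concatenate([v, [_lns]]))
        r1 = minimize(fixed_lns, u0[:-1], method="L-BFGS-B",
                      options={"maxiter": maxiter, "maxfun": 50 * maxiter})
        # stage 2: joint refinement including the noise scale
        u1 = np.concatenate([r1.x, [u0[-1]]])
        r = minimize(neg_log_post, u1, method="L-BFGS-B",
                     options={"maxiter": maxiter, "maxfun": 50 * maxiter})
        if res is None or r.fun < res.fun:
            res = r
    u_hat = res.x
    nat = spec.unpack(u_hat)
    free_energy = _laplace_free_energy(neg_log_post, u_hat)

    pred = predict(nat)
    if np.std(pred) > 0 and np.std(y) > 0:
        r_fit = float(np.corrcoef(pred, y)[0, 1])
    else:
        r_fit = 0.0

    f_null = float("nan")
    prob = float("nan")
    if fit_null:
        f_null = fit_null_model(y, designs, space, priors=priors,
                                hemodynamics=hemodynamics).free_energy
        prob = float(expit(free_energy - f_null))

    if model == NULL:
        params = PRFParameters(model=GAUSSIAN, beta_e=0.0,
                               baseline=float(np.mean(nat["baselines"])))
    else:
        params = PRFParameters(
            model=model, x0=float(nat["x0"]), y0=float(nat["y0"]),
            sigma_x=float(nat["sx"]), sigma_y=float(nat["sy"]),
            sigma_d=float(nat["sd"]), beta_e=float(nat["be"]),
            beta_i=float(nat["bi"]), baseline=float(np.mean(nat["baselines"])),
        )
    if not res.success:
        logger.debug("voxel %s (%s): optimizer stopped early (%s)",
                     voxel_id, model, res.message)
    return VoxelFitResult(
        voxel_id=voxel_id, params=params, free_energy=free_energy,
        posterior_model_prob=prob, r_fit=r_fit, converged=bool(res.success),
        model=model, free_energy_null=f_null,
        run_baselines=tuple(float(b) for b in nat["baselines"]),
        run_drifts=tuple(float(m) for m in nat["drifts"]),
        noise_sd=float(np.exp(np.clip(nat["lns"], -20, 20))),
    )


def fit_null_model(
    bold: np.ndarray,
    designs: StimulusDesign | Sequence[StimulusDesign],
    space: HandSpace,
    priors: PriorSpec | None = None,
    hemodynamics: HemodynamicModel | None = None,
) -> VoxelFitResult:
    """Fit the intercept + per-run linear drift null model."""
    y = np.asarray(bold, dtype=float)
    designs = [designs] if isinstance(designs, StimulusDesign) else list(designs)
    priors = priors or PriorSpec()
    hemodynamics = hemodynamics or DoubleGammaHRF()
    problem = _ForwardProblem(designs, space, hemodynamics)
    spec = _ModelSpec(NULL, len(designs), space, priors)
    predict, neg_log_post = _make_objective(problem, spec, y)
    baselines = []
    drifts = []
    off = 0
    for n, reg in zip(problem.run_lengths, problem.drift_regs):
        seg = y[off:off + n]
        A = np.column_stack([np.ones(n), reg])
        coef, _, _, _ = np.linalg.lstsq(A, seg, rcond=None)
        baselines.append(float(coef[0]))
        drifts.append(float(coef[1]))
        off += n
    resid_sd = max(float(np.std(y)), 1e-6)
    u0 = spec.pack(PRFParameters(), baselines, drifts, float(np.log(resid_sd)))
    res = minimize(neg_log_post, u0, method="L-BFGS-B", options={"maxiter": 200})
    nat = spec.unpack(res.x)
    free_energy = _laplace_free_energy(neg_log_post, res.x)
    params = PRFParameters(model=GAUSSIAN, beta_e=0.0,
                           baseline=float(np.mean(nat["baselines"])))
    return VoxelFitResult(
        voxel_id=-1, params=params, free_energy=free_energy,
        posterior_model_prob=float("nan"), r_fit=0.0,
        converged=bool(res.success), model=NULL,
        run_baselines=tuple(float(b) for b in nat["baselines"]),
        run_drifts=tuple(float(m) for m in nat["drifts"]),
        noise_sd=float(np.exp(np.clip(nat["lns"], -20, 20))),
    )


def fit_voxels(
    bold: np.ndarray,
    designs: StimulusDesign | Sequence[StimulusDesign],
    space: HandSpace,
    model: str = GAUSSIAN,
    hemodynamics: HemodynamicModel | None = None,
    priors: PriorSpec | None = None,
    voxel_ids: Sequence[int] | None = None,
    **kwargs,
) -> list[VoxelFitResult]:
    """Fit every row of a voxel x time matrix."""
    bold = np.atleast_2d(np.asarray(bold, dtype=float))
    if voxel_ids is None:
        voxel_ids = range(bold.shape[0])
    return [fit_voxel(bold[i], designs, space, model=model,
                      hemodynamics=hemodynamics, priors=priors,
                      voxel_id=vid, **kwargs)
            for i, vid in enumerate(voxel_ids)]


def compare_models(g: VoxelFitResult, d: VoxelFitResult) -> ModelComparison:
    """Gaussian-vs-DoG verdict from the free-energy difference.

    Differences of at least 3 (about a 20:1 Bayes factor) decide the model;
    anything smaller is indeterminate.
    """
    if g.voxel_id != d.voxel_id:
        raise ValueError("model comparison requires the same voxel")
    delta = float(g.free_energy - d.free_energy)
    if delta >= EVIDENCE_BAND:
        verdict = "gaussian"
    elif delta <= -EVIDENCE_BAND:
        verdict = "dog"
    else:
        verdict = "indeterminate"
    return ModelComparison(voxel_id=g.voxel_id, delta_f=delta, verdict=verdict)
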