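"""First-order structured latent curve model for longitudinal counts.

The model, per individual i with assessments at bin times t_w and sampled
exposures u_w:

    y_iw | b_i ~ NB2(mu_iw, phi_w)
    log mu_iw = log u_iw + f(t_w; beta) + Lambda(t_w; beta) b_i
    b_i ~ MVN(0, T)

where f is the linear--linear growth function with changepoint gamma and
zero-order continuity (growth.eval_growth), Lambda is the SLCM basis of
first-order partial derivatives evaluated at the population parameters
(growth.basis_matrix; the random changepoint deviation is centered at
zero), and phi_w follows a population-level dispersion trajectory
(dispersion.dispersion_at) or is free per occasion.

Estimation is marginal maximum likelihood: the per-individual integral over
b_i is approximated by adaptive Gauss--Hermite quadrature (nodes recentered
at each individual's posterior mode and rescaled by the posterior
curvature), and the marginal log-likelihood is maximized directly by
L-BFGS-B on an unconstrained internal parameterization (log-Cholesky /
log-sd for T, a bounded logistic transform for the changepoint, positivity
transforms for the dispersion coefficients).

The analytic gradient treats the adaptive centering/scaling as fixed when
differentiating (the standard fixed-adaptation approximation); for
non-diagonal T the outer gradient falls back to finite differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.linalg import cho_solve
from scipy.optimize import minimize
from scipy.special import digamma, expit, gammaln, logit, logsumexp
from sklearn.base import BaseEstimator

from .dispersion import DispersionTrajectory, dispersion_at, n_dispersion_params
from .growth import PARAM_ORDER, GrowthParams, GrowthSpec, basis_matrix, count_free_growth_params, eval_growth
from .measurement import BinnedData, bin_and_dedupe

__all__ = [
    "QuadSpec",
    "SLCMParams",
    "FitResult",
    "IdentificationReport",
    "linear_predictor",
    "individual_loglik",
    "fit_slcm",
    "robust_se",
    "check_identification",
    "eb_random_effects",
    "population_curve",
    "compare_to_average",
    "SLCM",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class QuadSpec:
    """Gauss--Hermite quadrature settings.

    nodes_per_dim: 1-D node count (7 by default; 15 matches the reference
    software default). adaptive: recenter/rescale at the per-individual
    posterior mode. prune: drop multi-dimensional nodes whose joint
    (normalized) weight falls below this threshold.
    """

    nodes_per_dim: int = 7
    adaptive: bool = True
    prune: float = 1e-10

    def __post_init__(self):
        if self.nodes_per_dim < 1:
            raise ValueError("nodes_per_dim must be >= 1")


@dataclass(frozen=True)
class SLCMParams:
    """Population parameters of the count SLCM."""

    fixed: GrowthParams
    T: np.ndarray
    disp: DispersionTrajectory
    random_effect_mask: tuple = (True, True, True, True)

    def __post_init__(self):
        T = np.atleast_2d(np.asarray(self.T, dtype=float))
        d = int(sum(self.random_effect_mask))
        if T.shape != (d, d):
            raise ValueError(f"T must be {d}x{d} for this random-effect mask")
        if not np.allclose(T, T.T):
            raise ValueError("T must be symmetric")
        eig = np.linalg.eigvalsh(T)
        if np.any(eig < -1e-10):
            raise ValueError("T must be positive semidefinite")
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "random_effect_mask", tuple(bool(m) for m in self.random_effect_mask))

    @property
    def random_effect_names(self):
        return tuple(n for n, m in zip(PARAM_ORDER, self.random_effect_mask) if m)


@dataclass
class IdentificationReport:
    p_mean: int
    p_cov: int
    obs_mean: int
    obs_cov: int
    mean_status: str
    cov_status: str
    overall: str


@dataclass
class FitResult:
    """MML estimates and everything needed to report them."""

    params: SLCMParams
    loglik: float
    aic: float
    bic: float
    n_params: int
    se: dict
    robust_se: dict
    converged: bool
    message: str
    n_individuals: int
    n_obs: int
    W: int
    eb: pd.DataFrame
    identification: IdentificationReport
    niter: int = 0
    theta_internal: np.ndarray | None = None
    estimates: dict = field(default_factory=dict)
    history: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# linear predictor
# ---------------------------------------------------------------------------

def linear_predictor(record, growth_params: GrowthParams) -> float:
    """eta = log(exposure) + f(t) for one record (mapping Series or dict).

    The exposure offset enters with coefficient fixed at one, so the
    expected count is exactly proportional to exposure.
    """
    u = float(record["exposure"])
    if u <= 0:
        raise ValueError("exposure must be > 0")
    t = float(record["bin_t"]) if "bin_t" in record else float(record["t"])
    return float(np.log(u) + eval_growth(t, growth_params))


# ---------------------------------------------------------------------------
# internal parameterization
# ---------------------------------------------------------------------------

class _Parameterization:
    """Maps the unconstrained internal vector theta <-> natural parameters.

    Layout: [beta0, beta1, beta3, x_gamma | T block | dispersion block].
    gamma = lo + (hi - lo) * expit(x_gamma); T via log-sd (diagonal) or
    log-Cholesky (full); expdecay via (log(delta1-delta3), logit(delta2),
    log(delta3)); loglinear raw; free via log phi per bin.
    """

    def __init__(self, disp_form, re_structure, mask, gamma_lo, gamma_hi, bin_times):
        self.disp_form = disp_form
        self.re_structure = re_structure
        self.mask = tuple(bool(m) for m in mask)
        self.d = int(sum(self.mask))
        self.gamma_lo = float(gamma_lo)
        self.gamma_hi = float(gamma_hi)
        self.bin_times = np.asarray(bin_times, dtype=float)
        self.n_growth = 4
        if re_structure == "diagonal":
            self.n_T = self.d
        elif re_structure == "full":
            self.n_T = self.d * (self.d + 1) // 2
        else:
            raise ValueError("re_structure must be 'diagonal' or 'full'")
        self.n_disp = {"free": len(self.bin_times), "loglinear": 2, "expdecay": 3}[disp_form]
        self.n_params = self.n_growth + self.n_T + self.n_disp

    # -- growth block
    def gamma_from_x(self, x):
        return self.gamma_lo + (self.gamma_hi - self.gamma_lo) * expit(x)

    def x_from_gamma(self, g):
        frac = np.clip((g - self.gamma_lo) / (self.gamma_hi - self.gamma_lo), 1e-6, 1 - 1e-6)
        return float(logit(frac))

    def dgamma_dx(self, x):
        e = expit(x)
        return (self.gamma_hi - self.gamma_lo) * e * (1.0 - e)

    def growth(self, theta) -> GrowthParams:
        b0, b1, b3, xg = theta[:4]
        return GrowthParams(beta0=b0, beta1=b1, beta3=b3, gamma_cp=self.gamma_from_x(xg))

    # -- T block
    def chol_T(self, theta) -> np.ndarray:
        block = theta[self.n_growth:self.n_growth + self.n_T]
        L = np.zeros((self.d, self.d))
        if self.re_structure == "diagonal":
            np.fill_diagonal(L, np.exp(block))
        else:
            idx = 0
            for i in range(self.d):
                for j in range(i + 1):
                    L[i, j] = np.exp(block[idx]) if i == j else block[idx]
                    idx += 1
        return L

    def T_matrix(self, theta) -> np.ndarray:
        L = self.chol_T(theta)
        return L @ L.T

    # -- dispersion block
    def disp(self, theta) -> DispersionTrajectory:
        block = theta[self.n_growth + self.n_T:]
        if self.disp_form == "loglinear":
            return DispersionTrajectory("loglinear", tuple(block))
        if self.disp_form == "expdecay":
            a, b, c = block
            d3 = np.exp(c)
            return DispersionTrajectory("expdecay", (d3 + np.exp(a), expit(b), d3))
        return DispersionTrajectory("free", tuple(np.exp(block)), times=tuple(self.bin_times))

    def phi_at(self, theta, times):
        return dispersion_at(times, self.disp(theta))

    def dphi_dblock(self, theta, times):
        """Jacobian d phi(t) / d internal dispersion block, shape (len(times), n_disp)."""
        t = np.asarray(times, dtype=float)
        block = theta[self.n_growth + self.n_T:]
        if self.disp_form == "loglinear":
            phi = np.exp(block[0] + block[1] * t)
            return np.column_stack([phi, t * phi])
        if self.disp_form == "expdecay":
            a, b, c = block
            d2 = expit(b)
            da = np.exp(a) * d2**t
            db = np.exp(a) * t * d2**t * (1.0 - d2)
            dc = np.full_like(t, np.exp(c))
            return np.column_stack([da, db, dc])
        # free: phi_w = exp(x_w), one-hot per bin
        J = np.zeros((len(t), self.n_disp))
        for j, tb in enumerate(self.bin_times):
            J[t == tb, j] = np.exp(block[j])
        return J

    # -- packing
    def pack(self, params: SLCMParams) -> np.ndarray:
        theta = np.zeros(self.n_params)
        g = params.fixed
        theta[:4] = [g.beta0, g.beta1, g.beta3, self.x_from_gamma(g.gamma_cp)]
        T = params.T
        if self.re_structure == "diagonal":
            theta[4:4 + self.n_T] = 0.5 * np.log(np.maximum(np.diag(T), 1e-12))
        else:
            L = np.linalg.cholesky(T + 1e-10 * np.eye(self.d))
            idx = 0
            vals = []
            for i in range(self.d):
                for j in range(i + 1):
                    vals.append(np.log(max(L[i, j], 1e-8)) if i == j else L[i, j])
            theta[4:4 + self.n_T] = vals
        c = params.disp.coeffs
        off = self.n_growth + self.n_T
        if self.disp_form == "loglinear":
            theta[off:] = c
        elif self.disp_form == "expdecay":
            d1, d2, d3 = c
            theta[off:] = [np.log(d1 - d3), logit(d2), np.log(d3)]
        else:
            theta[off:] = np.log(np.maximum(c, 1e-8))
        return theta

    def unpack(self, theta) -> SLCMParams:
        return SLCMParams(
            fixed=self.growth(theta),
            T=self.T_matrix(theta),
            disp=self.disp(theta),
            random_effect_mask=self.mask,
        )

    # -- natural-scale reporting
    def natural_names(self):
        names = ["beta0", "beta1", "beta3", "gamma_cp"]
        re_names = [n for n, m in zip(PARAM_ORDER, self.mask) if m]
        if self.re_structure == "diagonal":
            names += [f"var_{n}" for n in re_names]
        else:
            for i in range(self.d):
                for j in range(i + 1):
                    names.append(f"T[{re_names[i]},{re_names[j]}]")
        if self.disp_form == "loglinear":
            names += ["d0", "d1"]
        elif self.disp_form == "expdecay":
            names += ["delta1", "delta2", "delta3"]
        else:
            names += [f"phi[{tb:g}]" for tb in self.bin_times]
        return names

    def natural(self, theta) -> np.ndarray:
        g = self.growth(theta)
        vals = [g.beta0, g.beta1, g.beta3, g.gamma_cp]
        T = self.T_matrix(theta)
        if self.re_structure == "diagonal":
            vals += list(np.diag(T))
        else:
            for i in range(self.d):
                for j in range(i + 1):
                    vals.append(T[i, j])
        vals += list(self.disp(theta).coeffs)
        return np.array(vals)


# ---------------------------------------------------------------------------
# quadrature grid
# ---------------------------------------------------------------------------

def _gh_grid(nodes_per_dim: int, d: int, prune: float):
    """Tensor-product Gauss--Hermite grid (physicists') with weight pruning.

    Returns z (K, d) and logw (K,) where logw = sum_j log w_j + |z|^2 (the
    exp(|z|^2) reweighting of the adaptive transform folded in). Pruning is
    on the joint *normalized* weights prod w_j / pi^{d/2}.
    """
    x, w = hermgauss(nodes_per_dim)
    logw1 = np.log(w)
    grids = np.meshgrid(*([x] * d), indexing="ij")
    z = np.column_stack([g.ravel() for g in grids])
    lw = np.zeros(len(z))
    for j in range(d):
        lw += logw1[np.searchsorted(x, z[:, j])]
    if prune > 0 and d > 1:
        keep = lw - 0.5 * d * np.log(np.pi) >= np.log(prune)
        z, lw = z[keep], lw[keep]
    return z, lw + np.sum(z**2, axis=1)


# ---------------------------------------------------------------------------
# marginal likelihood engine
# ---------------------------------------------------------------------------

class _AGHEngine:
    """Vectorized AGH marginal log-likelihood and its analytic gradient.

    Data are stored sorted by individual; per-individual sums use
    ``np.add.reduceat`` over contiguous blocks.
    """

    def __init__(self, table: pd.DataFrame, par: _Parameterization, quad: QuadSpec):
        df = table.sort_values(["id", "bin_t"]).reset_index(drop=True)
        self.ids, ind = np.unique(df["id"].to_numpy(), return_inverse=True)
        order = np.argsort(ind, kind="stable")
        df = df.iloc[order].reset_index(drop=True)
        self.ind = ind[order]
        self.N = len(self.ids)
        self.y = df["count"].to_numpy(dtype=float)
        self.logu = np.log(df["exposure"].to_numpy(dtype=float))
        self.t = df["bin_t"].to_numpy(dtype=float)
        self.n_obs = len(df)
        self.starts = np.searchsorted(self.ind, np.arange(self.N))
        self.par = par
        self.quad = quad
        self.z, self.logw = _gh_grid(quad.nodes_per_dim, par.d, quad.prune)
        self.K = len(self.z)
        self._b_warm = np.zeros((self.N, par.d))
        self.mask_idx = [i for i, m in enumerate(par.mask) if m]

    # -- per-theta precomputations
    def _prep(self, theta):
        g = self.par.growth(theta)
        Lam_full = basis_matrix(self.t, g)           # (n_obs, 4)
        Lam = Lam_full[:, self.mask_idx]             # (n_obs, d)
        c = self.logu + eval_growth(self.t, g)       # base eta at b = 0
        phi = self.par.phi_at(theta, self.t)
        r = 1.0 / phi
        L_T = self.par.chol_T(theta)
        Tinv = cho_solve((L_T, True), np.eye(self.par.d))
        logdetT = 2.0 * np.sum(np.log(np.diag(L_T)))
        A = gammaln(self.y + r) - gammaln(r) - gammaln(self.y + 1.0) + r * np.log(r)
        return g, Lam, c, r, L_T, Tinv, logdetT, A

    def _group(self, arr):
        """Sum an (n_obs, ...) array into (N, ...) per-individual blocks."""
        return np.add.reduceat(arr, self.starts, axis=0)

    # -- posterior modes, batched Newton
    def _modes(self, Lam, c, r, Tinv, logdetT):
        d = self.par.d
        b = self._b_warm.copy()
        y = self.y

        def h_parts(b):
            eta = c + np.einsum("od,od->o", Lam, b[self.ind])
            L = np.logaddexp(np.log(r), eta)
            lp = y * eta - (y + r) * L          # node-dependent part only
            quad_form = np.einsum("nd,de,ne->n", b, Tinv, b)
            h = self._group(lp) - 0.5 * quad_form
            return h, eta, L

        h, eta, L = h_parts(b)
        for _ in range(40):
            p = np.exp(eta - L)
            s = y - (y + r) * p
            w = (y + r) * p * (1.0 - p)
            grad = self._group(Lam * s[:, None]) - b @ Tinv
            H = self._group(w[:, None, None] * Lam[:, :, None] * Lam[:, None, :]) + Tinv
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
            gnorm = np.abs(grad).max()
            if gnorm < 1e-8:
                break
            # step halving on individuals whose objective decreases
            alpha = np.ones(self.N)
            for _half in range(8):
                b_new = b + alpha[:, None] * step
                h_new, eta_new, L_new = h_parts(b_new)
                bad = h_new < h - 1e-12
                if not np.any(bad):
                    break
                alpha[bad] *= 0.5
            b, h, eta, L = b_new, h_new, eta_new, L_new
        # curvature at the mode
        p = np.exp(eta - L)
        w = (y + r) * p * (1.0 - p)
        H = self._group(w[:, None, None] * Lam[:, :, None] * Lam[:, None, :]) + Tinv
        self._b_warm = b
        return b, H

    # -- main evaluation
    def evaluate(self, theta, want_grad=False):
        par = self.par
        d = par.d
        g, Lam, c, r, L_T, Tinv, logdetT, A = self._prep(theta)
        y = self.y

        m, H = self._modes(Lam, c, r, Tinv, logdetT)
        # C = H^{-1} = M M^T with M = inv(chol(H))^T
        R = np.linalg.cholesky(H)                      # (N, d, d) lower
        I = np.broadcast_to(np.eye(d), (self.N, d, d))
        Rinv = np.linalg.solve(R, I)                   # R^{-1}
        M = np.transpose(Rinv, (0, 2, 1))              # C = M M^T
        logdetM = -np.log(np.diagonal(R, axis1=1, axis2=2)).sum(axis=1)

        # nodes: B[i,k,:] = m_i + sqrt(2) * M_i z_k
        B = m[:, None, :] + np.sqrt(2.0) * np.einsum("nde,ke->nkd", M, self.z)
        Bo = B[self.ind]                               # (n_obs, K, d)
        eta = c[:, None] + np.einsum("od,okd->ok", Lam, Bo)
        L = np.logaddexp(np.log(r)[:, None], eta)
        lp = A[:, None] + y[:, None] * eta - (y + r)[:, None] * L
        # prior at the nodes
        quad_form = np.einsum("nkd,de,nke->nk", B, Tinv, B)
        logprior = -0.5 * (d * _LOG2PI + logdetT + quad_form)
        inner = self._group(lp) + logprior + self.logw[None, :]
        l_i = 0.5 * d * np.log(2.0) + logdetM + logsumexp(inner, axis=1)
        total = float(l_i.sum())
        if not want_grad:
            return total, l_i, None

        # --- analytic gradient, fixed-adaptation approximation -------------
        P = np.exp(inner - l_i[:, None] + 0.5 * d * np.log(2.0) + logdetM[:, None])
        Po = P[self.ind]                               # (n_obs, K)
        p = np.exp(eta - L)
        s = y[:, None] - (y + r)[:, None] * p          # dlp/deta

        grad = np.zeros((self.N, par.n_params))
        after = (self.t > g.gamma_cp).astype(float)
        min_t = np.minimum(self.t, g.gamma_cp)
        max_t = np.maximum(0.0, self.t - g.gamma_cp)
        names = [n for n, mm in zip(PARAM_ORDER, par.mask) if mm]
        j_b1 = names.index("beta1") if "beta1" in names else None
        j_b3 = names.index("beta3") if "beta3" in names else None
        j_g = names.index("gamma") if "gamma" in names else None

        def acc_obs(idx, deta):
            grad[:, idx] = (self._group(s * deta) * P).sum(axis=1)

        # beta0
        acc_obs(0, np.ones((self.n_obs, 1)))
        # beta1: d eta = min(t, g) + b_gamma * 1[t > g]
        deta = min_t[:, None] + (after[:, None] * Bo[:, :, j_g] if j_g is not None else 0.0)
        acc_obs(1, deta)
        # beta3: d eta = max(0, t - g) - b_gamma * 1[t > g]
        deta = max_t[:, None] - (after[:, None] * Bo[:, :, j_g] if j_g is not None else 0.0)
        acc_obs(2, deta)
        # gamma (chain through the logistic transform)
        slope_diff = g.beta1 - g.beta3
        deta = slope_diff + (Bo[:, :, j_b1] if j_b1 is not None else 0.0) \
            - (Bo[:, :, j_b3] if j_b3 is not None else 0.0)
        deta = after[:, None] * deta
        grad[:, 3] = (self._group(s * deta) * P).sum(axis=1) * self.par.dgamma_dx(theta[3])

        # T block (diagonal only; full T uses numeric fallback upstream)
        if par.re_structure == "diagonal":
            sig2 = np.exp(2.0 * theta[4:4 + d])
            for j in range(d):
                dgp = -1.0 + B[:, :, j] ** 2 / sig2[j]   # d logprior / d log sigma_j
                grad[:, 4 + j] = (P * dgp).sum(axis=1)

        # dispersion block
        D0 = digamma(y + r) - digamma(r) + np.log(r) + 1.0
        dlp_dr = D0[:, None] - L - (y + r)[:, None] * np.exp(-L)
        dlp_dphi = -(r**2)[:, None] * dlp_dr
        Jphi = self.par.dphi_dblock(theta, self.t)       # (n_obs, n_disp)
        for j in range(par.n_disp):
            contrib = dlp_dphi * Jphi[:, j][:, None]
            grad[:, 4 + par.n_T + j] = (self._group(contrib) * P).sum(axis=1)

        return total, l_i, grad

    def evaluate_total(self, theta):
        """Loglik plus *total* gradient only — the optimization hot path.

        Same fixed-adaptation gradient as ``evaluate(want_grad=True)`` but
        with the per-individual grouping collapsed into observation-level
        sums, which avoids all (n_obs, K) reduceats in the gradient.
        """
        par = self.par
        d = par.d
        g, Lam, c, r, L_T, Tinv, logdetT, A = self._prep(theta)
        y = self.y

        m, H = self._modes(Lam, c, r, Tinv, logdetT)
        R = np.linalg.cholesky(H)
        I = np.broadcast_to(np.eye(d), (self.N, d, d))
        M = np.transpose(np.linalg.solve(R, I), (0, 2, 1))
        logdetM = -np.log(np.diagonal(R, axis1=1, axis2=2)).sum(axis=1)

        B = m[:, None, :] + np.sqrt(2.0) * np.einsum("nde,ke->nkd", M, self.z)
        Bo = B[self.ind]
        eta = c[:, None] + np.einsum("od,okd->ok", Lam, Bo)
        L = np.logaddexp(np.log(r)[:, None], eta)
        lp = A[:, None] + y[:, None] * eta - (y + r)[:, None] * L
        quad_form = np.einsum("nkd,de,nke->nk", B, Tinv, B)
        logprior = -0.5 * (d * _LOG2PI + logdetT + quad_form)
        inner = self._group(lp) + logprior + self.logw[None, :]
        l_i = 0.5 * d * np.log(2.0) + logdetM + logsumexp(inner, axis=1)
        total = float(l_i.sum())

        P = np.exp(inner - l_i[:, None] + 0.5 * d * np.log(2.0) + logdetM[:, None])
        Po = P[self.ind]
        SP = Po * (y[:, None] - (y + r)[:, None] * np.exp(eta - L))  # Po * dlp/deta
        S1 = SP.sum(axis=1)

        grad = np.zeros(par.n_params)
        after = (self.t > g.gamma_cp).astype(float)
        min_t = np.minimum(self.t, g.gamma_cp)
        max_t = np.maximum(0.0, self.t - g.gamma_cp)
        names = [n for n, mm in zip(PARAM_ORDER, par.mask) if mm]
        j_b1 = names.index("beta1") if "beta1" in names else None
        j_b3 = names.index("beta3") if "beta3" in names else None
        j_g = names.index("gamma") if "gamma" in names else None

        SG = (SP * Bo[:, :, j_g]).sum(axis=1) if j_g is not None else 0.0
        SB1 = (SP * Bo[:, :, j_b1]).sum(axis=1) if j_b1 is not None else 0.0
        SB3 = (SP * Bo[:, :, j_b3]).sum(axis=1) if j_b3 is not None else 0.0
        grad[0] = S1.sum()
        grad[1] = min_t @ S1 + (after * SG).sum() if j_g is not None else min_t @ S1
        grad[2] = max_t @ S1 - (after * SG).sum() if j_g is not None else max_t @ S1
        gamma_term = (g.beta1 - g.beta3) * (after @ S1)
        if j_b1 is not None:
            gamma_term += (after * SB1).sum()
        if j_b3 is not None:
            gamma_term -= (after * SB3).sum()
        grad[3] = gamma_term * self.par.dgamma_dx(theta[3])

        if par.re_structure == "diagonal":
            sig2 = np.exp(2.0 * theta[4:4 + d])
            for j in range(d):
                grad[4 + j] = (P * (-1.0 + B[:, :, j] ** 2 / sig2[j])).sum()

        D0 = digamma(y + r) - digamma(r) + np.log(r) + 1.0
        dlp_dr = D0[:, None] - L - (y + r)[:, None] * np.exp(-L)
        w_disp = -(r**2) * (Po * dlp_dr).sum(axis=1)     # sum_k Po * dlp/dphi
        Jphi = self.par.dphi_dblock(theta, self.t)
        grad[4 + par.n_T:] = w_disp @ Jphi

        return total, grad


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _as_table(data) -> pd.DataFrame:
    if isinstance(data, BinnedData):
        return data.table
    df = pd.DataFrame(data)
    if "bin_t" not in df.columns:
        raise ValueError("data must carry a 'bin_t' column (use bin_and_dedupe first)")
    return df[["id", "bin_t", "count", "exposure"]]


def _make_par(table, dispersion, re_structure, mask, gamma_margin) -> _Parameterization:
    times = np.sort(table["bin_t"].unique())
    lo = float(times.min()) + gamma_margin
    hi = float(times.max()) - gamma_margin
    if not hi > lo:
        raise ValueError("time range too short to place a changepoint")
    return _Parameterization(dispersion, re_structure, mask, lo, hi, times)


def individual_loglik(records, params: SLCMParams, quad: QuadSpec | None = None) -> float:
    """Marginal log-likelihood contribution of a single individual.

    With T = 0 the integral degenerates to the fixed-effects-only
    log-likelihood; otherwise adaptive Gauss--Hermite quadrature over the
    masked random effects is used.
    """
    quad = quad or QuadSpec()
    df = pd.DataFrame(records)
    if len(df) < 1:
        raise ValueError("individual must have at least one record")
    from .distributions import nb2_logpmf

    t = df["bin_t"].to_numpy(dtype=float)
    y = df["count"].to_numpy()
    u = df["exposure"].to_numpy(dtype=float)
    phi = dispersion_at(t, params.disp)
    if np.allclose(params.T, 0.0):
        mu = u * np.exp(eval_growth(t, params.fixed))
        return float(nb2_logpmf(y, mu, phi).sum())
    # shared engine with a single individual; gamma bounds wide enough to
    # represent the supplied changepoint exactly
    df = df.assign(id=0)
    mask = params.random_effect_mask
    times = np.sort(np.unique(t))
    hi = max(float(times.max()), params.fixed.gamma_cp) + 10.0
    par = _Parameterization(params.disp.form, "full", mask, -1.0, hi, times)
    engine = _AGHEngine(df, par, quad)
    theta = par.pack(params)
    total, _, _ = engine.evaluate(theta)
    return total


def check_identification(spec: GrowthSpec, disp, random_effect_mask, W: int,
                         re_structure: str = "full") -> IdentificationReport:
    """Count free parameters against available observations.

    The mean structure offers W observed means against the free population
    growth parameters; the covariance structure offers W(W+1)/2 observed
    (co)variances against the unique elements of T plus the dispersion
    coefficients. Both must be overidentified for the model to be.
    """
    if W < 1:
        raise ValueError("W must be >= 1")
    if isinstance(disp, str):
        disp = DispersionTrajectory(disp, {"loglinear": (0.0, 0.0), "expdecay": (1.0, 0.5, 0.5)}.get(disp, ()))
    p_mean = count_free_growth_params(spec)
    d = int(sum(random_effect_mask))
    n_T = d * (d + 1) // 2 if re_structure == "full" else d
    p_cov = n_T + n_dispersion_params(disp, W)
    obs_mean = W
    obs_cov = W * (W + 1) // 2

    def status(obs, p):
        if obs > p:
            return "overidentified"
        if obs == p:
            return "just-identified"
        return "underidentified"

    ms, cs = status(obs_mean, p_mean), status(obs_cov, p_cov)
    overall = "overidentified" if ms == cs == "overidentified" else (
        "underidentified" if "underidentified" in (ms, cs) else "just-identified"
    )
    return IdentificationReport(p_mean, p_cov, obs_mean, obs_cov, ms, cs, overall)


# -- initialization ----------------------------------------------------------

def _initial_values(table, par: _Parameterization):
    """Data-driven starting values.

    beta/gamma from a two-segment least-squares fit to pooled bin-level log
    rates over a grid of candidate knots; T diagonals at 0.1*|fixed effect|;
    dispersion from per-bin method-of-moments estimates.
    """
    agg = table.groupby("bin_t").agg(y=("count", "sum"), u=("exposure", "sum"))
    tb = agg.index.to_numpy(dtype=float)
    lr = np.log((agg["y"].to_numpy() + 0.5) / (agg["u"].to_numpy() + 1.0))
    # candidate knots at bin midpoints: off the bin grid, where the
    # piecewise-linear likelihood surface is differentiable
    mids = 0.5 * (tb[:-1] + tb[1:]) if len(tb) > 1 else tb
    candidates = mids[(mids > par.gamma_lo) & (mids < par.gamma_hi)]
    if len(candidates) == 0:
        candidates = np.array([(par.gamma_lo + par.gamma_hi) / 2.0])
    best = None
    for gcand in candidates:
        X = np.column_stack([np.ones_like(tb), np.minimum(tb, gcand), np.maximum(0.0, tb - gcand)])
        coef, res, *_ = np.linalg.lstsq(X, lr, rcond=None)
        sse = float(((X @ coef - lr) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, coef, gcand)
    _, coef, gamma0 = best
    growth0 = GrowthParams(float(coef[0]), float(coef[1]), float(coef[2]), float(gamma0))

    # per-bin method-of-moments dispersion
    phis = {}
    for bt, grp in table.groupby("bin_t"):
        y = grp["count"].to_numpy(dtype=float)
        u = grp["exposure"].to_numpy(dtype=float)
        mu = u * np.exp(growth0.beta0 + growth0.beta1 * min(bt, gamma0)
                        + growth0.beta3 * max(0.0, bt - gamma0))
        denom = float((mu**2).sum())
        num = float(((y - mu) ** 2 - mu).sum())
        phis[bt] = float(np.clip(num / denom if denom > 0 else 0.5, 0.02, 20.0))
    tb_sorted = np.sort(list(phis))
    phi_arr = np.array([phis[b] for b in tb_sorted])

    if par.disp_form == "expdecay":
        tail = float(np.median(phi_arr[len(phi_arr) * 2 // 3:])) if len(phi_arr) > 2 else float(phi_arr[-1])
        d3 = max(tail, 0.05)
        d1 = max(float(phi_arr[0]), d3 * 1.5 + 0.05)
        disp0 = DispersionTrajectory("expdecay", (d1, 0.9, d3))
    elif par.disp_form == "loglinear":
        cf = np.polyfit(tb_sorted, np.log(phi_arr), 1)
        disp0 = DispersionTrajectory("loglinear", (float(cf[1]), float(cf[0])))
    else:
        disp0 = DispersionTrajectory("free", tuple(phi_arr), times=tuple(tb_sorted))

    fixed_arr = np.array([growth0.beta0, growth0.beta1, growth0.beta3, gamma0])
    diag = np.maximum(0.1 * np.abs(fixed_arr), 1e-3)[list(np.nonzero(par.mask)[0])]
    T0 = np.diag(diag)
    return SLCMParams(fixed=growth0, T=T0, disp=disp0, random_effect_mask=par.mask)


# -- fitting ----------------------------------------------------------------

def fit_slcm(
    data,
    growth_spec: GrowthSpec | None = None,
    dispersion: str = "expdecay",
    re_structure: str = "diagonal",
    random_effects=PARAM_ORDER,
    quad: QuadSpec | None = None,
    init: SLCMParams | None = None,
    gamma_margin: float = 3.0,
    max_iter: int = 300,
    tol: float = 1e-9,
    compute_se: bool = True,
    robust: bool = True,
    refine_changepoint: bool = True,
    verbose: bool = False,
) -> FitResult:
    """Fit the count SLCM by marginal maximum likelihood.

    ``data`` is a binned long-format table (id, bin_t, count, exposure) or a
    BinnedData. The changepoint is kept inside
    [min t + gamma_margin, max t - gamma_margin] by a logistic transform.
    ``refine_changepoint`` adds warm restarts from the adjacent knot
    regions, guarding against local optima created by the likelihood's
    discontinuities in gamma at bin times. Deterministic given data, init
    and options.
    """
    if growth_spec is not None and (growth_spec.n_phases != 2 or growth_spec.degrees != (1, 1)
                                    or growth_spec.continuity != (0,)):
        raise NotImplementedError("only the zero-order-continuity linear-linear trajectory is fit")
    quad = quad or QuadSpec()
    table = _as_table(data)
    mask = tuple(n in tuple(random_effects) for n in PARAM_ORDER)
    par = _make_par(table, dispersion, re_structure, mask, gamma_margin)
    engine = _AGHEngine(table, par, quad)
    init_params = init if init is not None else _initial_values(table, par)
    theta0 = par.pack(init_params)

    use_analytic = re_structure == "diagonal"
    history = []

    if use_analytic:
        def objective(theta):
            total, grad = engine.evaluate_total(theta)
            history.append(total)
            return -total, -grad
        jac = True
    else:
        def objective(theta):
            total, _, _ = engine.evaluate(theta)
            history.append(total)
            return -total
        jac = None

    bounds = [(None, None)] * 3 + [(-10.0, 10.0)]
    if re_structure == "diagonal":
        bounds += [(-8.0, 4.0)] * par.n_T
    else:
        idx = 0
        for i in range(par.d):
            for j in range(i + 1):
                bounds.append((-8.0, 4.0) if i == j else (None, None))
                idx += 1
    # keep exp/expit transforms of the dispersion block away from overflow
    if dispersion == "expdecay":
        bounds += [(-10.0, 6.0), (-12.0, 12.0), (-10.0, 6.0)]
    elif dispersion == "free":
        bounds += [(-8.0, 5.0)] * par.n_disp
    else:
        bounds += [(None, None)] * par.n_disp

    opts = {"maxiter": max_iter, "ftol": tol, "gtol": 1e-6, "maxcor": 20}

    def _polish(x0):
        """L-BFGS with restarts until the objective is restart-stable.

        A fresh start clears line-search failures (ABNORMAL) and the
        premature ftol stops L-BFGS is prone to on this surface.
        """
        out = minimize(objective, x0, jac=jac, method="L-BFGS-B",
                       bounds=bounds, options=opts)
        stable = False
        for _ in range(4):
            again = minimize(objective, out.x, jac=jac, method="L-BFGS-B",
                             bounds=bounds, options=opts)
            stable = again.fun > out.fun - 1e-7
            if again.fun < out.fun:
                out = again
            if stable:
                break
        # at a kink-top optimum (gamma on a bin time) the gradient is
        # discontinuous and L-BFGS reports ABNORMAL; restart-stability is
        # the meaningful convergence signal there
        out.restart_stable = stable
        return out

    res = _polish(theta0)

    if refine_changepoint:
        # the likelihood is discontinuous in gamma at bin times, so a local
        # optimizer can be trapped one knot region away from the optimum;
        # retry from the adjacent regions (warm-started) and keep the best,
        # iterating until no adjacent region improves (fixed point)
        half_bin = 0.5 * float(np.min(np.diff(np.unique(engine.t)))) if engine.n_obs > 1 else 1.5
        for _round in range(3):
            improved = False
            g_hat = par.gamma_from_x(res.x[3])
            for g_try in (g_hat - half_bin, g_hat + half_bin):
                if not (par.gamma_lo < g_try < par.gamma_hi):
                    continue
                theta_try = res.x.copy()
                theta_try[3] = par.x_from_gamma(g_try)
                alt = _polish(theta_try)
                if alt.fun < res.fun - 1e-8:
                    res = alt
                    improved = True
            if not improved:
                break
    theta = res.x
    total, l_i, grads = engine.evaluate(theta, want_grad=use_analytic)
    params = par.unpack(theta)

    converged = (bool(res.success) or np.abs(res.jac).max() < 1e-2
                 or bool(getattr(res, "restart_stable", False)))
    message = str(res.message)
    gamma = params.fixed.gamma_cp
    if gamma < par.gamma_lo + 0.05 or gamma > par.gamma_hi - 0.05:
        converged = False
        message += " | changepoint pinned at its boundary"

    k = par.n_params
    aic = -2.0 * total + 2.0 * k
    bic = -2.0 * total + k * np.log(engine.N)

    se = {}
    rob = {}
    if compute_se and converged:
        pinned = np.array([
            (lb is not None and x <= lb + 1e-6) or (ub is not None and x >= ub - 1e-6)
            for x, (lb, ub) in zip(theta, bounds)
        ])
        se, rob, _cov = _standard_errors(engine, par, theta, grads if use_analytic else None,
                                         robust=robust, pinned=pinned)
    elif compute_se and not converged:
        warnings.warn("fit did not converge; standard errors withheld")

    eb = _eb_table(engine, par, theta)
    gspec = growth_spec or GrowthSpec()
    ident = check_identification(gspec, params.disp, mask, len(np.unique(engine.t)),
                                 re_structure=re_structure)

    return FitResult(
        params=params, loglik=total, aic=aic, bic=bic, n_params=k,
        se=se, robust_se=rob, converged=converged, message=message,
        n_individuals=engine.N, n_obs=engine.n_obs, W=len(np.unique(engine.t)),
        eb=eb, identification=ident, niter=int(res.nit),
        theta_internal=theta,
        estimates=dict(zip(par.natural_names(), par.natural(theta))),
        history=history,
    )


def _num_grad(engine, theta, step=1e-5):
    """Central finite-difference gradient of the total marginal loglik."""
    g = np.zeros_like(theta)
    for j in range(len(theta)):
        h = step * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        fp, _, _ = engine.evaluate(tp)
        fm, _, _ = engine.evaluate(tm)
        g[j] = (fp - fm) / (2.0 * h)
    return g


def _standard_errors(engine, par, theta, grads, robust=True, step=1e-4, pinned=None):
    """Model-based and cluster-robust SEs on the natural scale.

    Bread: inverse observed information (numeric Hessian of the marginal
    loglik, by finite differences of the analytic per-individual gradients
    when available). Meat: sum of outer products of per-individual scores.
    Natural-scale SEs via the delta method with a numeric Jacobian of the
    natural-parameter map. Parameters pinned at an optimizer bound
    (typically variance components collapsed to zero) are profiled out of
    the information matrix; their SEs propagate as zero.
    """
    P = len(theta)
    pinned = np.zeros(P, dtype=bool) if pinned is None else np.asarray(pinned, dtype=bool)

    def total_grad(th):
        if par.re_structure == "diagonal":
            return engine.evaluate_total(th)[1]
        return _num_grad(engine, th)

    H = np.zeros((P, P))
    for j in range(P):
        h = step * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (total_grad(tp) - total_grad(tm)) / (2.0 * h)
    H = 0.5 * (H + H.T)
    info = -H
    active = ~pinned
    bread = np.zeros((P, P))
    info_a = info[np.ix_(active, active)]
    w, V = np.linalg.eigh(info_a)
    tol_w = 1e-10 * max(w.max(), 1.0)
    if np.any(w <= tol_w):
        # weakly identified directions (typically a variance component at
        # coarse quadrature): drop them from the inverse rather than
        # inverting noise or negative curvature
        warnings.warn("observed information not positive definite; "
                      "dropping its non-positive directions")
    winv = np.where(w > tol_w, 1.0 / np.maximum(w, tol_w), 0.0)
    bread_a = (V * winv) @ V.T
    bread[np.ix_(active, active)] = bread_a

    if grads is None:
        # per-individual scores by finite differences of per-individual logliks
        G = np.zeros((engine.N, P))
        for j in range(P):
            h = step * (1.0 + abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            _, lp, _ = engine.evaluate(tp)
            _, lm, _ = engine.evaluate(tm)
            G[:, j] = (lp - lm) / (2.0 * h)
    else:
        G = grads
    meat = G.T @ G
    sandwich = bread @ meat @ bread

    # delta method to the natural scale
    J = np.zeros((len(par.natural(theta)), P))
    for j in range(P):
        h = 1e-6 * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        J[:, j] = (par.natural(tp) - par.natural(tm)) / (2.0 * h)
    names = par.natural_names()
    se_nat = np.sqrt(np.maximum(np.diag(J @ bread @ J.T), 0.0))
    rob_nat = np.sqrt(np.maximum(np.diag(J @ sandwich @ J.T), 0.0))
    se = dict(zip(names, se_nat))
    rob = dict(zip(names, rob_nat)) if robust else {}
    return se, rob, (bread, sandwich, J)


def robust_se(fit: FitResult, data, quad: QuadSpec | None = None) -> dict:
    """Recompute cluster-robust (sandwich) SEs for a converged fit."""
    if not fit.converged:
        raise ValueError("robust SEs require a converged fit")
    quad = quad or QuadSpec()
    table = _as_table(data)
    par = _make_par(table, fit.params.disp.form,
                    "diagonal" if _is_diagonal(fit.params.T) else "full",
                    fit.params.random_effect_mask, 3.0)
    # keep the same gamma bounds the estimates imply
    engine = _AGHEngine(table, par, quad)
    theta = par.pack(fit.params)
    use_analytic = par.re_structure == "diagonal"
    _, _, grads = engine.evaluate(theta, want_grad=use_analytic)
    _, rob, _ = _standard_errors(engine, par, theta, grads)
    return rob


def _is_diagonal(T):
    return np.allclose(T, np.diag(np.diag(T)))


def _eb_table(engine: _AGHEngine, par: _Parameterization, theta) -> pd.DataFrame:
    """Posterior modes and Laplace SDs of the random effects, per individual."""
    g, Lam, c, r, L_T, Tinv, logdetT, A = engine._prep(theta)
    m, H = engine._modes(Lam, c, r, Tinv, logdetT)
    C = np.linalg.inv(H)
    sds = np.sqrt(np.maximum(np.diagonal(C, axis1=1, axis2=2), 0.0))
    names = [n for n, mm in zip(PARAM_ORDER, par.mask) if mm]
    out = {"id": engine.ids}
    for j, n in enumerate(names):
        out[f"b_{n}"] = m[:, j]
        out[f"sd_b_{n}"] = sds[:, j]
    return pd.DataFrame(out)


def eb_random_effects(fit: FitResult, records, quad: QuadSpec | None = None) -> pd.DataFrame:
    """Posterior mode and curvature of b_i for the supplied records.

    Falls back to b = 0 (the prior mode) for individuals whose mode search
    fails; with T -> 0 the posterior collapses to 0 for everyone.
    """
    quad = quad or QuadSpec()
    table = _as_table(pd.DataFrame(records))
    times = np.sort(table["bin_t"].unique())
    hi = max(float(times.max()), fit.params.fixed.gamma_cp) + 10.0
    par = _Parameterization(
        fit.params.disp.form,
        "diagonal" if _is_diagonal(fit.params.T) else "full",
        fit.params.random_effect_mask, -1.0, hi, times)
    engine = _AGHEngine(table, par, quad)
    theta = par.pack(fit.params)
    return _eb_table(engine, par, theta)


def population_curve(fit_or_params, times, per_exposure: float = 1000.0) -> pd.DataFrame:
    """Expected counts per stated exposure along the population trajectory.

    The returned frame's ``attrs`` carry the shifted changepoint
    (gamma + time origin) in months.
    """
    params = fit_or_params.params if isinstance(fit_or_params, FitResult) else fit_or_params
    g = params.fixed
    t = np.atleast_1d(np.asarray(times, dtype=float))
    expected = per_exposure * np.exp(eval_growth(t, g))
    df = pd.DataFrame({"t": t, "age_months": t + 18.0, "expected_count": expected})
    df.attrs["shifted_changepoint_months"] = g.gamma_cp + 18.0
    df.attrs["per_exposure"] = per_exposure
    return df


def compare_to_average(fit: FitResult) -> dict:
    """Classify individuals against the population curve at entry and in phase 1.

    Signs of the empirical-Bayes intercept and phase-1 slope effects define
    above/below-average classes; exact zeros land in a separate "at" class.
    Returns per-individual flags, the cross-tab of counts and percentages.
    """
    eb = fit.eb
    for col in ("b_beta0", "b_beta1"):
        if col not in eb.columns:
            raise ValueError("comparison requires random effects on beta0 and beta1")

    def cls(x):
        return np.where(x > 0, "above", np.where(x < 0, "below", "at"))

    flags = pd.DataFrame({
        "id": eb["id"],
        "entry": cls(eb["b_beta0"].to_numpy()),
        "phase1_slope": cls(eb["b_beta1"].to_numpy()),
    })
    counts = flags.groupby(["entry", "phase1_slope"]).size().rename("n").reset_index()
    counts["percent"] = 100.0 * counts["n"] / len(flags)
    return {"flags": flags, "crosstab": counts, "n": len(flags)}


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class SLCM(BaseEstimator):
    """Count SLCM estimator (scikit-learn style).

    Accepts a long-format DataFrame with columns id, count, exposure and
    either bin_t (months since origin) or age_months; raw ages are binned
    with the study-design rules first.

    Fitted attributes: ``result_`` (FitResult) plus the usual shortcuts
    ``params_``, ``loglik_``, ``aic_``, ``bic_``, ``se_``, ``robust_se_``,
    ``converged_``, ``eb_``, ``identification_``.
    """

    def __init__(self, dispersion="expdecay", re_structure="diagonal",
                 random_effects=PARAM_ORDER, nodes_per_dim=7, adaptive=True,
                 bin_width=3.0, origin=18.0, max_age=72.0, min_exposure=25,
                 gamma_margin=3.0, max_iter=300, tol=1e-9,
                 compute_se=True, robust=True, random_state=None):
        self.dispersion = dispersion
        self.re_structure = re_structure
        self.random_effects = random_effects
        self.nodes_per_dim = nodes_per_dim
        self.adaptive = adaptive
        self.bin_width = bin_width
        self.origin = origin
        self.max_age = max_age
        self.min_exposure = min_exposure
        self.gamma_margin = gamma_margin
        self.max_iter = max_iter
        self.tol = tol
        self.compute_se = compute_se
        self.robust = robust
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None, init: SLCMParams | None = None):
        df = pd.DataFrame(X)
        if "bin_t" not in df.columns:
            rng = np.random.default_rng(self.random_state)
            binned = bin_and_dedupe(df, bin_width=self.bin_width, origin=self.origin,
                                    max_age=self.max_age, min_exposure=self.min_exposure, rng=rng)
            df = binned.table
        self.result_ = fit_slcm(
            df, dispersion=self.dispersion, re_structure=self.re_structure,
            random_effects=self.random_effects,
            quad=QuadSpec(self.nodes_per_dim, self.adaptive),
            init=init, gamma_margin=self.gamma_margin,
            max_iter=self.max_iter, tol=self.tol,
            compute_se=self.compute_se, robust=self.robust,
        )
        r = self.result_
        self.params_ = r.params
        self.loglik_ = r.loglik
        self.aic_ = r.aic
        self.bic_ = r.bic
        self.se_ = r.se
        self.robust_se_ = r.robust_se
        self.converged_ = r.converged
        self.eb_ = r.eb
        self.identification_ = r.identification
        self.n_obs_ = r.n_obs
        self.n_individuals_ = r.n_individuals
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Population-level expected counts for rows with bin_t/age and exposure."""
        df = pd.DataFrame(X)
        if "bin_t" in df.columns:
            t = df["bin_t"].to_numpy(dtype=float)
        else:
            t = df["age_months"].to_numpy(dtype=float) - self.origin
        u = df["exposure"].to_numpy(dtype=float)
        return u * np.exp(eval_growth(t, self.params_.fixed))

    def score(self, X=None, y=None) -> float:
        """Mean marginal log-likelihood per individual of the fitted data."""
        return self.loglik_ / self.result_.n_individuals

    def population_curve(self, times, per_exposure: float = 1000.0) -> pd.DataFrame:
        return population_curve(self.result_, times, per_exposure)

    def compare_to_average(self) -> dict:
        return compare_to_average(self.result_)
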