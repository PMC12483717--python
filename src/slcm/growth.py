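"""Piecewise growth trajectories and the structured-latent-curve basis.

The workhorse is the two-phase linear--linear trajectory with an estimated
changepoint ``gamma`` and zero-order continuity at the knot, written with
min/max operators so continuity holds identically:

    f(t) = beta0 + beta1 * min(t, gamma) + beta3 * max(0, t - gamma)

Time ``t`` is months since the origin (age 18 months in the motivating
child-language design), so the phase-1 intercept ``beta0`` is the log rate
per unit exposure at the origin. The eliminated phase-2 intercept is the
derived quantity ``beta2 = beta0 + beta1*gamma``.

The structured-latent-curve (SLCM) basis matrix holds the first-order
partial derivatives of f with respect to the free growth parameters,
evaluated at population values with the random changepoint deviation
centered at zero; it is the factor-loading matrix through which random
effects (including the changepoint's) enter the linear predictor linearly.

``GrowthSpec`` also supports more general piecewise-polynomial descriptions
for parameter counting and the linear/nonlinear classification rule: a
growth parameter is *linear* iff the partial derivative of f with respect
to it does not itself contain the parameter. The rule is applied
symbolically (sympy), not looked up from a table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

__all__ = [
    "GrowthSpec",
    "GrowthParams",
    "PARAM_ORDER",
    "eval_growth",
    "basis_matrix",
    "classify_linearity",
    "count_free_growth_params",
]

#: canonical ordering of the free parameters of the continuity-constrained
#: linear-linear trajectory (also the random-effect ordering everywhere).
PARAM_ORDER = ("beta0", "beta1", "beta3", "gamma")


@dataclass(frozen=True)
class GrowthSpec:
    """Declarative description of a piecewise-polynomial trajectory.

    Parameters
    ----------
    n_phases : int
        Number of phases (>= 1; a single phase has no knot).
    degrees : tuple of int
        Polynomial degree per phase (default: degree 1 everywhere).
    continuity : tuple of int
        Continuity order at each of the ``n_phases - 1`` knots: -1 for a
        discontinuous jump, 0 for zero-order continuity (phases meet).
        Orders >= 1 are representable but not supported by the evaluators.
    time_origin : float
        Chronological age (months) mapped to t = 0.
    """

    n_phases: int = 2
    degrees: tuple = ()
    continuity: tuple = ()
    time_origin: float = 18.0

    def __post_init__(self):
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")
        degrees = self.degrees or tuple([1] * self.n_phases)
        continuity = self.continuity if self.n_phases > 1 and self.continuity != () else tuple([0] * (self.n_phases - 1))
        if len(degrees) != self.n_phases:
            raise ValueError("one degree per phase required")
        if len(continuity) != self.n_phases - 1:
            raise ValueError("one continuity order per knot required")
        for c, d in zip(continuity, degrees[1:]):
            if c < -1:
                raise ValueError("continuity order must be >= -1")
            if c > d - 1 and c > 0:
                raise ValueError("continuity order too high for the phase degree")
        object.__setattr__(self, "degrees", degrees)
        object.__setattr__(self, "continuity", continuity)

    # -- symbolic construction -------------------------------------------------

    def symbolic(self):
        """Return (expr, t, params) for f(t) built with Min/Max operators.

        Phase j >= 2 contributes powers of max(0, t - gamma_{j-1}); under a
        continuity order c at the knot the lowest c+1 coefficients of that
        phase are eliminated (for c = 0, its intercept). Discontinuous knots
        (-1) keep a free jump term carried by a Heaviside step.
        """
        t = sp.Symbol("t", nonnegative=True)
        params = []
        expr = sp.Integer(0)
        knots = [sp.Symbol(f"gamma{k+1}", positive=True) for k in range(self.n_phases - 1)]
        # phase 1 polynomial in min(t, gamma1)
        u = sp.Min(t, knots[0]) if knots else t
        for k in range(self.degrees[0] + 1):
            c = sp.Symbol(f"beta1_{k}")
            params.append(c)
            expr += c * u**k
        for j in range(1, self.n_phases):
            lo = knots[j - 1]
            hi = knots[j] if j < self.n_phases - 1 else None
            v = sp.Max(0, t - lo)
            if hi is not None:
                v = sp.Min(v, hi - lo)
            cont = self.continuity[j - 1]
            k_start = cont + 1 if cont >= 0 else 0
            if cont == -1:
                # free jump at the knot
                jump = sp.Symbol(f"beta{j+1}_0")
                params.append(jump)
                expr += jump * sp.Heaviside(t - lo, 0)
                k_start = 1
            for k in range(k_start, self.degrees[j] + 1):
                c = sp.Symbol(f"beta{j+1}_{k}")
                params.append(c)
                expr += c * v**k
        params.extend(knots)
        return expr, t, params


@dataclass(frozen=True)
class GrowthParams:
    """Free parameters of the continuity-constrained linear-linear trajectory.

    beta0
        Phase-1 intercept: log expected count per unit exposure at t = 0.
    beta1, beta3
        Phase-1 / phase-2 slopes per month (log-rate scale).
    gamma_cp
        Changepoint, months since the time origin (>= 0).
    """

    beta0: float
    beta1: float
    beta3: float
    gamma_cp: float

    def __post_init__(self):
        if not self.gamma_cp >= 0:
            raise ValueError("gamma_cp must be >= 0")

    @property
    def beta2(self) -> float:
        """Derived phase-2 intercept implied by zero-order continuity."""
        return self.beta0 + self.beta1 * self.gamma_cp

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta3, self.gamma_cp])


def eval_growth(t, params: GrowthParams):
    """Evaluate f(t) = beta0 + beta1*min(t, gamma) + beta3*max(0, t - gamma).

    ``t`` is months since the origin and must be >= 0 (ages before the
    origin are outside the model's support).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0 (months since the time origin)")
    g = params.gamma_cp
    return params.beta0 + params.beta1 * np.minimum(t, g) + params.beta3 * np.maximum(0.0, t - g)


def basis_matrix(times, pop_params: GrowthParams) -> np.ndarray:
    """SLCM factor-loading matrix: d f / d (beta0, beta1, beta3, gamma).

    Row for time t:

        [1,  min(t, gamma),  max(0, t - gamma),  (beta1 - beta3) * 1[t > gamma]]

    evaluated at the population parameters with the random changepoint
    deviation centered at zero. At t == gamma exactly the changepoint column
    takes the left value (0), consistent with max(0, t - gamma) = 0 there.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    g = pop_params.gamma_cp
    after = t > g
    cols = [
        np.ones_like(t),
        np.minimum(t, g),
        np.maximum(0.0, t - g),
        (pop_params.beta1 - pop_params.beta3) * after.astype(float),
    ]
    return np.column_stack(cols)


def classify_linearity(spec: GrowthSpec) -> dict:
    """Tag each free growth parameter 'linear' or 'nonlinear'.

    Applies the derivative-inclusion rule symbolically: a parameter is
    linear iff d f / d theta does not contain theta.
    """
    expr, _t, params = spec.symbolic()
    tags = {}
    for p in params:
        d = sp.diff(expr, p)
        tags[str(p)] = "nonlinear" if p in d.free_symbols else "linear"
    return tags


def count_free_growth_params(spec: GrowthSpec) -> int:
    """Number of free per-individual growth parameters after continuity eliminations."""
    _expr, _t, params = spec.symbolic()
    return len(params)
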