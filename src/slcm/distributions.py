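"""Counting-process distribution kernel.

Poisson and NB2 (negative binomial with quadratic variance function) in the
mean--dispersion parameterization used throughout the package:

    Poisson:  Var(Y) = mu
    NB2:      Var(Y) = mu + phi * mu**2,   phi > 0

``phi`` is the dispersion ("nuisance") parameter; the more common "size"
parameterization of the negative binomial relates to it by ``size = 1/phi``.
The Poisson distribution is the limiting NB2 distribution as ``phi -> 0``.

All computation is in log space via ``scipy.special.gammaln``; no factorials
are ever formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, xlogy

__all__ = [
    "CountDistributionSpec",
    "poisson_logpmf",
    "nb2_logpmf",
    "logpmf",
    "variance_function",
    "sample_count",
    "support_upper",
]


@dataclass(frozen=True)
class CountDistributionSpec:
    """A counting-process family plus (for NB2) its dispersion parameter.

    Parameters
    ----------
    family : {"poisson", "nb2"}
    dispersion : float, optional
        The ``phi`` in ``Var = mu + phi*mu**2``. Required (and strictly
        positive) for ``"nb2"``; must be absent for ``"poisson"``.
    """

    family: str
    dispersion: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "nb2"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "nb2":
            if self.dispersion is None:
                raise ValueError("nb2 requires a dispersion parameter")
            if not self.dispersion > 0:
                raise ValueError("nb2 dispersion must be > 0")
        elif self.dispersion is not None:
            raise ValueError("poisson takes no dispersion parameter")


def _check_y(y):
    y = np.asarray(y)
    if not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("counts must be integers")
    if np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    return y.astype(float)


def _check_pos(x, name):
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError(f"{name} must be strictly positive")
    return x


def poisson_logpmf(y, mu):
    """log P(Y = y) for Y ~ Poisson(mu)."""
    y = _check_y(y)
    mu = _check_pos(mu, "mu")
    return xlogy(y, mu) - mu - gammaln(y + 1.0)


def nb2_logpmf(y, mu, phi):
    """log P(Y = y) for Y ~ NB2(mu, phi), Var = mu + phi*mu**2.

    Uses the gamma-function form with size r = 1/phi:

        P(Y=y) = Gamma(y+r) / (Gamma(r) y!) * (r/(r+mu))^r * (mu/(r+mu))^y
    """
    y = _check_y(y)
    mu = _check_pos(mu, "mu")
    phi = _check_pos(phi, "phi")
    r = 1.0 / phi
    log_rpmu = np.logaddexp(np.log(r), np.log(mu))
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * (np.log(r) - log_rpmu)
        + y * (np.log(mu) - log_rpmu)
    )


def logpmf(y, mu, spec: CountDistributionSpec):
    """Family-dispatching log pmf."""
    if spec.family == "poisson":
        return poisson_logpmf(y, mu)
    return nb2_logpmf(y, mu, spec.dispersion)


def variance_function(mu, spec: CountDistributionSpec):
    """Model-implied variance at mean ``mu``: mu (Poisson) or mu + phi*mu**2 (NB2)."""
    mu = _check_pos(mu, "mu")
    if spec.family == "poisson":
        return mu
    return mu + spec.dispersion * mu**2


def sample_count(mu, spec: CountDistributionSpec, rng: np.random.Generator, size=None):
    """Draw counts from the specified family.

    NB2 draws use the gamma--Poisson mixture: lambda ~ Gamma(shape=1/phi,
    scale=phi*mu), Y | lambda ~ Poisson(lambda), whose marginal is NB2(mu, phi).
    """
    mu = _check_pos(mu, "mu")
    if not isinstance(rng, np.random.Generator):
        raise TypeError("rng must be a numpy.random.Generator")
    if spec.family == "poisson":
        return rng.poisson(mu, size=size)
    r = 1.0 / spec.dispersion
    lam = rng.gamma(shape=r, scale=spec.dispersion * mu, size=size)
    return rng.poisson(lam)


def support_upper(mu, spec: CountDistributionSpec, tail: float = 1e-12, cap: int = 10_000_000) -> int:
    """Smallest y such that the pmf's mass beyond y is < ``tail``.

    Grows the support geometrically; used by normalization checks and the
    marginal KLD summation.
    """
    hi = max(int(10 * (mu + 1)), 20)
    while hi < cap:
        ys = np.arange(hi + 1)
        mass = np.exp(logpmf(ys, mu, spec)).sum()
        if 1.0 - mass < tail:
            return hi
        hi *= 2
    return cap
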