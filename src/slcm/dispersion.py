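"""Population-level trajectories for the time-varying NB2 dispersion.

The NB2 dispersion parameter phi_w is occasion-specific but shared across
individuals. Rather than estimating one free phi per measurement occasion
(W parameters), a parametric trajectory can be imposed:

  loglinear   phi(t) = exp(d0 + d1 * t)                      (2 coefficients)
  expdecay    phi(t) = delta3 + (delta1 - delta3) * delta2**t (3 coefficients)

In the exponential-decay-with-nonzero-asymptote form, delta1 is exactly the
dispersion at the time origin (t = 0, age 18 months), delta2 in (0, 1) is
the monthly decay factor of the excess over the asymptote, and delta3 > 0
is the asymptote approached as children age beyond early childhood. With
delta1 > delta3 > 0 the trajectory is strictly decreasing and positive.

The "free" form keeps one dispersion parameter per occasion; its per-bin
values live with the model that estimates them (coeffs here may carry the
fitted values alongside their bin times for reporting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DispersionTrajectory", "dispersion_at", "n_dispersion_params"]

_FORMS = ("free", "loglinear", "expdecay")


@dataclass(frozen=True)
class DispersionTrajectory:
    """A dispersion-trajectory form plus its coefficient vector.

    coeffs: () for free (or the fitted per-bin phis, paired with ``times``);
    (d0, d1) for loglinear; (delta1, delta2, delta3) for expdecay.
    """

    form: str
    coeffs: tuple = ()
    times: tuple = ()  # only for form="free" with per-bin values attached

    def __post_init__(self):
        if self.form not in _FORMS:
            raise ValueError(f"unknown dispersion trajectory form {self.form!r}")
        c = tuple(float(x) for x in self.coeffs)
        object.__setattr__(self, "coeffs", c)
        object.__setattr__(self, "times", tuple(float(x) for x in self.times))
        if self.form == "loglinear":
            if len(c) != 2:
                raise ValueError("loglinear requires coefficients (d0, d1)")
        elif self.form == "expdecay":
            if len(c) != 3:
                raise ValueError("expdecay requires coefficients (delta1, delta2, delta3)")
            d1, d2, d3 = c
            if not (d1 > d3 > 0):
                raise ValueError("expdecay requires delta1 > delta3 > 0")
            if not (0 < d2 < 1):
                raise ValueError("expdecay decay factor delta2 must lie in (0, 1)")
        else:  # free
            if len(self.times) != len(c):
                raise ValueError("free form: times and coeffs must pair up")
            if c and not all(x > 0 for x in c):
                raise ValueError("per-bin dispersions must be > 0")


def dispersion_at(times, traj: DispersionTrajectory):
    """Evaluate phi(t) >= 0 at the requested times (months since origin)."""
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if traj.form == "loglinear":
        d0, d1 = traj.coeffs
        return np.exp(d0 + d1 * t)
    if traj.form == "expdecay":
        delta1, delta2, delta3 = traj.coeffs
        return delta3 + (delta1 - delta3) * delta2**t
    # free: exact lookup against the attached bin times
    if not traj.times:
        raise ValueError("free trajectory carries no per-bin values to evaluate")
    lookup = dict(zip(traj.times, traj.coeffs))
    try:
        return np.array([lookup[x] for x in t])
    except KeyError as e:
        raise ValueError(f"no free dispersion value stored for time {e.args[0]}") from None


def n_dispersion_params(traj: DispersionTrajectory, W: int) -> int:
    """Free dispersion-specific parameters: W (free), 2 (loglinear), 3 (expdecay)."""
    if W < 1:
        raise ValueError("W must be >= 1")
    return {"free": W, "loglinear": 2, "expdecay": 3}[traj.form]
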