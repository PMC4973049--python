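"""Parameter distributions for probabilistic sensitivity analysis.

Every uncertain model input is described by a :class:`DistributionSpec` — a
small declarative record of a distribution family plus its parameters, with
the raw derivation inputs (counts, mean/SE) kept alongside so the arithmetic
that produced the parameters can be audited and re-run.

Families
--------
``beta``
    Shape parameters ``(a, b)``.  Probabilities derived from event counts use
    ``Beta(r, n - r)`` so the distribution mean equals the crude proportion
    ``r/n`` exactly; the Bayesian ``Beta(r+1, n-r+1)`` variant is available via
    :func:`beta_from_counts`.
``gamma``
    ``(shape, scale)``.  Costs reported as mean and standard error are fitted
    by method of moments: ``shape = (mean/se)**2``, ``scale = se**2/mean``.
``normal``
    ``(mean, se)`` — used for log odds ratios and population utility norms.
``fixed``
    ``(value,)`` — degenerate; every draw returns the value.
``logit-normal``
    ``(mu, sigma)`` on the logit scale; used for intervention effectiveness
    (see :mod:`poisonprev.effectiveness`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

FAMILIES = ("beta", "gamma", "normal", "fixed", "logit-normal")


class DegenerateCountsError(ValueError):
    """Raised when event counts cannot parameterise a Beta distribution."""


class InvalidMomentsError(ValueError):
    """Raised when a mean/SE pair cannot parameterise a Gamma distribution."""


class DistributionSupportError(ValueError):
    """Raised when a sampled value falls outside the parameter's support."""


@dataclass(frozen=True)
class DistributionSpec:
    """One uncertain parameter: family, parameters and optional derivation."""

    family: str
    params: tuple[float, ...]
    derivation: Optional[dict] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        p = self.params
        if self.family == "beta":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ValueError(f"beta requires two positive shapes, got {p}")
        elif self.family == "gamma":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise InvalidMomentsError(
                    f"gamma requires positive shape and scale, got {p}"
                )
        elif self.family == "normal":
            if len(p) != 2 or p[1] < 0:
                raise ValueError(f"normal requires (mean, se>=0), got {p}")
        elif self.family == "fixed":
            if len(p) != 1:
                raise ValueError(f"fixed requires a single value, got {p}")
        elif self.family == "logit-normal":
            if len(p) != 2 or p[1] < 0:
                raise ValueError(f"logit-normal requires (mu, sigma>=0), got {p}")

    def mean(self) -> float:
        """Analytic mean (logit-normal returns the back-transformed median,
        the conventional point estimate for quantile-fitted posteriors)."""
        a: float
        if self.family == "beta":
            a, b = self.params
            return a / (a + b)
        if self.family == "gamma":
            shape, scale = self.params
            return shape * scale
        if self.family == "normal":
            return self.params[0]
        if self.family == "fixed":
            return self.params[0]
        # logit-normal: median
        return float(expit(self.params[0]))

    def sd(self) -> float:
        if self.family == "beta":
            a, b = self.params
            return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1))))
        if self.family == "gamma":
            shape, scale = self.params
            return float(np.sqrt(shape) * scale)
        if self.family == "normal":
            return self.params[1]
        if self.family == "fixed":
            return 0.0
        raise NotImplementedError("no closed-form sd for logit-normal")

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        """Draw from the distribution. ``fixed`` broadcasts its value."""
        if self.family == "beta":
            return rng.beta(self.params[0], self.params[1], size=size)
        if self.family == "gamma":
            return rng.gamma(self.params[0], self.params[1], size=size)
        if self.family == "normal":
            return rng.normal(self.params[0], self.params[1], size=size)
        if self.family == "fixed":
            return np.broadcast_to(np.float64(self.params[0]), () if size is None else size).copy()
        return expit(rng.normal(self.params[0], self.params[1], size=size))


def beta_from_counts(successes: float, total: float, *, bayesian: bool = False) -> DistributionSpec:
    """Beta distribution from ``successes`` out of ``total`` trials.

    The default ``Beta(r, n - r)`` parameterisation has mean exactly ``r/n``,
    matching the point estimates printed alongside each derivation.  With
    ``bayesian=True`` the uniform-prior posterior ``Beta(r+1, n-r+1)`` is
    returned instead.
    """
    if not 0 < successes < total:
        raise DegenerateCountsError(
            f"need 0 < successes < total, got {successes}/{total}"
        )
    a, b = (successes + 1, total - successes + 1) if bayesian else (successes, total - successes)
    return DistributionSpec(
        "beta", (float(a), float(b)),
        derivation={"successes": successes, "total": total, "bayesian": bayesian},
    )


def gamma_from_mean_se(mean: float, se: float) -> DistributionSpec:
    """Method-of-moments Gamma for a cost reported as mean and SE (GBP)."""
    if mean <= 0 or se <= 0:
        raise InvalidMomentsError(f"need positive mean and se, got {mean}, {se}")
    shape = (mean / se) ** 2
    scale = se**2 / mean
    return DistributionSpec("gamma", (shape, scale), derivation={"mean": mean, "se": se})


def beta_from_mean_se(mean: float, se: float) -> DistributionSpec:
    """Method-of-moments Beta for a quantity on [0, 1] given mean and SE.

    Used for utility decrements, which are reported as a mean with an SE set
    to a fraction of the mean.
    """
    if not 0 < mean < 1:
        raise InvalidMomentsError(f"mean must lie in (0,1), got {mean}")
    var = se**2
    if var <= 0 or var >= mean * (1 - mean):
        raise InvalidMomentsError(f"variance {var} incompatible with mean {mean}")
    nu = mean * (1 - mean) / var - 1
    return DistributionSpec(
        "beta", (mean * nu, (1 - mean) * nu), derivation={"mean": mean, "se": se}
    )
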