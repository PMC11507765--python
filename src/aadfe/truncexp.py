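"""Truncated exponential distributions on [0, 1].

The maximum-entropy distribution on the unit interval with a fixed mean is
the truncated exponential

    p(x) = c * exp(-lambda * x),   c = lambda / (1 - exp(-lambda)),

where ``lambda`` is a real-valued shape parameter: ``lambda > 0`` gives a
monotonically decreasing density (mean < 0.5, deleterious-leaning),
``lambda < 0`` an increasing one, and ``lambda = 0`` the uniform
distribution.  This family underlies the type-specific DFEs: each of the
380 ordered amino-acid replacements gets one such distribution, fully
determined by its mean quantile.

All formulas use ``expm1``/``log1p`` forms and Taylor branches near
``lambda = 0`` so that the whole real line of shape parameters is handled
without catastrophic cancellation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TruncExpModel",
    "ScaleMap",
    "ConvergenceError",
    "density",
    "cdf",
    "inverse_cdf",
    "mean_of",
    "variance_of",
    "tail_probability",
    "fit_lambda_from_mean",
    "to_target_scale",
]

# below this |lambda|, closed forms are replaced by their Taylor series
_SMALL_LAMBDA = 1e-6

# Newton search is confined to this bracket; means outside
# (mean_of(500), mean_of(-500)) ~ (0.002, 0.998) are not representable
_LAMBDA_BRACKET = (-500.0, 500.0)


class ConvergenceError(RuntimeError):
    """Raised when the lambda-from-mean solver fails to converge."""


def _norm_const(lam: float) -> float:
    """Normalizing constant c = lambda / (1 - e^-lambda); c -> 1 as lambda -> 0."""
    if abs(lam) < _SMALL_LAMBDA:
        # lambda/(1 - e^-lambda) = 1/(1 - lambda/2 + lambda^2/6 - ...)
        return 1.0 / (1.0 - lam / 2.0 + lam * lam / 6.0)
    return lam / -math.expm1(-lam)


@dataclass(frozen=True)
class TruncExpModel:
    """A truncated exponential distribution on [0, 1] with shape ``lambda_``.

    Attributes
    ----------
    lambda_ : float
        Real-valued shape parameter.  ``lambda_ > 0`` iff the mean is
        below 0.5 (density decreasing); 0 gives the uniform distribution.
    norm_const : float
        The normalizing constant ``c`` (derived, not supplied).
    """

    lambda_: float
    norm_const: float = field(init=False)

    def __post_init__(self) -> None:
        lam = float(self.lambda_)
        if not math.isfinite(lam):
            raise ValueError(f"lambda must be finite, got {lam}")
        object.__setattr__(self, "lambda_", lam)
        object.__setattr__(self, "norm_const", _norm_const(lam))

    # -- distribution functions -------------------------------------------

    def pdf(self, x):
        x = _check_unit(x, "x")
        return self.norm_const * np.exp(-self.lambda_ * x)

    def cdf(self, x):
        x = _check_unit(x, "x")
        lam = self.lambda_
        if abs(lam) < _SMALL_LAMBDA:
            # x + lam*x(1-x)/2 to first order; adequate below the threshold
            return x + lam * x * (1.0 - x) / 2.0
        return np.expm1(-lam * x) / math.expm1(-lam)

    def ppf(self, u):
        u = _check_unit(u, "u")
        lam = self.lambda_
        if abs(lam) < _SMALL_LAMBDA:
            return u - lam * u * (1.0 - u) / 2.0
        # F^-1(u) = -ln(1 - u (1 - e^-lambda)) / lambda
        return -np.log1p(u * math.expm1(-lam)) / lam

    def sf(self, q):
        return 1.0 - self.cdf(q)

    def mean(self) -> float:
        return _mean(self.lambda_)

    def variance(self) -> float:
        return _variance(self.lambda_)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF sampling of ``size`` draws."""
        return self.ppf(rng.random(size))


def _check_unit(x, name: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"{name} must lie in [0, 1]")
    if np.ndim(x) == 0:
        return float(arr)
    return arr


def _mean(lam: float) -> float:
    # mu = 1/lambda - 1/(e^lambda - 1); limit 1/2 at lambda = 0
    if abs(lam) < _SMALL_LAMBDA:
        return 0.5 - lam / 12.0 + lam**3 / 720.0
    with np.errstate(over="ignore"):
        return 1.0 / lam - 1.0 / math.expm1(lam) if lam < 700 else 1.0 / lam


def _variance(lam: float) -> float:
    # sigma^2 = 1/lambda^2 - e^lambda/(e^lambda - 1)^2
    #         = 1/lambda^2 - 1/(2 sinh(lambda/2))^2 ; limit 1/12 at 0
    if abs(lam) < 1e-4:
        return 1.0 / 12.0 - lam * lam / 240.0
    try:
        s = 2.0 * math.sinh(lam / 2.0)
        return 1.0 / (lam * lam) - 1.0 / (s * s)
    except OverflowError:
        return 1.0 / (lam * lam)


# -- module-level operations ----------------------------------------------


def density(model: TruncExpModel, x):
    """Probability density c*e^(-lambda*x) at quantile ``x`` in [0, 1]."""
    return model.pdf(x)


def cdf(model: TruncExpModel, x):
    return model.cdf(x)


def inverse_cdf(model: TruncExpModel, u):
    return model.ppf(u)


def mean_of(model: TruncExpModel) -> float:
    """Expected quantile, strictly between 0 and 1."""
    return model.mean()


def variance_of(model: TruncExpModel) -> float:
    """Variance; an even function of lambda, peaking at 1/12 for lambda=0."""
    return model.variance()


def tail_probability(model: TruncExpModel, q) -> float:
    """P(X > q): the chance of exceeding the fitness-quantile threshold q."""
    return model.sf(q)


def fit_lambda_from_mean(
    mu: float, tol: float = 1e-10, max_iter: int = 100
) -> TruncExpModel:
    """Invert the mean function: find the model whose mean is ``mu``.

    The mean is strictly decreasing in lambda, so the root is unique.
    Safeguarded Newton iteration (the derivative of the mean with respect
    to lambda is minus the variance, an exponential-family identity) with
    bisection fallback whenever a Newton step leaves the current bracket.

    Raises
    ------
    ValueError
        If ``mu`` is not strictly inside (0, 1); no finite lambda exists.
    ConvergenceError
        If the solver does not reach ``tol`` within ``max_iter`` steps or
        ``mu`` is outside the representable bracket.
    """
    mu = float(mu)
    if not (0.0 < mu < 1.0):
        raise ValueError(f"mean must be strictly inside (0, 1), got {mu}")
    lo, hi = _LAMBDA_BRACKET
    if not (_mean(hi) < mu < _mean(lo)):
        raise ConvergenceError(
            f"mean {mu} outside the solvable range "
            f"({_mean(hi):.4g}, {_mean(lo):.4g})"
        )
    # linearization of the mean about lambda=0: mu ~ 1/2 - lambda/12
    lam = 12.0 * (0.5 - mu)
    lam = min(max(lam, lo), hi)
    for _ in range(max_iter):
        f = _mean(lam) - mu
        if abs(f) < tol:
            return TruncExpModel(lam)
        if f > 0.0:  # mean too large -> lambda too small
            lo = lam
        else:
            hi = lam
        step = f / _variance(lam)
        cand = lam + step
        lam = cand if lo < cand < hi else 0.5 * (lo + hi)
    raise ConvergenceError(
        f"no convergence to |mean error| < {tol} in {max_iter} iterations"
    )


def to_target_scale(model: TruncExpModel, scale: "ScaleMap", u):
    """Composite inverse CDF G^-1(u) = F^-1(trunc-exp ppf(u)).

    ``scale`` carries F^-1, the inverse CDF of the overall (all-types)
    distribution on the target measurement scale.  The induced type-specific
    distribution is the one minimizing KL divergence from the overall
    target-scale distribution subject to the mean-exceedance constraint.
    """
    return scale(model.ppf(u))


class ScaleMap:
    """Monotone map from [0, 1] to a target measurement scale (F^-1 of the
    overall DFE on that scale).

    Construct from a callable (checked for monotonicity on a grid) or from
    tabulated (probability, value) pairs, interpolated linearly.
    """

    def __init__(self, func: Callable, _checked: bool = False):
        if not _checked:
            grid = np.linspace(0.0, 1.0, 201)
            vals = np.asarray(func(grid), dtype=float)
            if vals.shape != grid.shape or np.any(np.diff(vals) < 0):
                raise ValueError("scale map must be monotone non-decreasing on [0, 1]")
        self._func = func

    def __call__(self, u):
        return self._func(u)

    @classmethod
    def identity(cls) -> "ScaleMap":
        return cls(lambda u: u, _checked=True)

    @classmethod
    def from_table(cls, probs: Sequence[float], values: Sequence[float]) -> "ScaleMap":
        p = np.asarray(probs, dtype=float)
        v = np.asarray(values, dtype=float)
        if p.ndim != 1 or p.shape != v.shape or len(p) < 2:
            raise ValueError("need two equal-length 1-d columns")
        order = np.argsort(p)
        p, v = p[order], v[order]
        if np.any(np.diff(v) < 0):
            raise ValueError("tabulated scale map must be monotone non-decreasing")
        return cls(lambda u: np.interp(u, p, v), _checked=True)

    @classmethod
    def from_tsv(cls, path) -> "ScaleMap":
        """Two-column TSV: probability <TAB> target value (header optional)."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", comment="#", header=None)
        if isinstance(df.iloc[0, 0], str):
            df = df.iloc[1:].astype(float)
        return cls.from_table(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())
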