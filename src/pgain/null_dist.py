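"""Closed-form null distribution of the conservative p-gain.

Under the null, each association p-value is Uniform(0, 1).  The conservative
("universal") p-gain takes the numerator p-value to be uncorrelated with the
ratio p-value, so the statistic is the ratio of two independent uniforms.
The convolution formula for density ratios yields the split density

    f(g) = 1/2          for 0 < g < 1
    f(g) = 1/(2 g^2)    for g >= 1

with distribution function

    F(g) = g/2          for 0 < g < 1
    F(g) = 1 - 1/(2 g)  for g >= 1.

Because any correlation between a metabolite and its ratio shrinks the spread
of the p-gain, critical values drawn from this null bound those of every
correlated setting from above.  With Bonferroni correction over B ratio tests
the critical p-gain is B/(2·alpha) — e.g. 10 at alpha = 0.05 with one test.

All tail quantities are exposed in log10 as well, so thresholds for B up to
1e12 tests never overflow.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "ConservativePGainNull",
    "density",
    "cdf",
    "quantile",
    "tail_probability",
    "critical_value",
    "critical_value_log10",
]


def _check_positive(g):
    g = np.asarray(g, dtype=float)
    if np.any(g <= 0):
        raise ValidationError("p-gain must be strictly positive")
    return g


class ConservativePGainNull:
    """Analytic null of the conservative p-gain (ratio of two iid uniforms).

    Stateless; array-valued methods broadcast over their inputs.
    """

    def pdf(self, g):
        """Split density: 1/2 below 1, 1/(2 g²) at and above 1."""
        g = _check_positive(g)
        out = np.where(g < 1.0, 0.5, 0.5 / (g * g))
        return out if out.ndim else float(out)

    density = pdf

    def cdf(self, g):
        """F(g) = g/2 below 1, 1 - 1/(2g) at and above 1."""
        g = _check_positive(g)
        out = np.where(g < 1.0, 0.5 * g, 1.0 - 0.5 / g)
        return out if out.ndim else float(out)

    def ppf(self, q):
        """Quantile function: 2q below the median, 1/(2(1-q)) above."""
        q = np.asarray(q, dtype=float)
        if np.any((q <= 0) | (q >= 1)):
            raise ValidationError("quantile level must lie strictly in (0, 1)")
        out = np.where(q < 0.5, 2.0 * q, 0.5 / (1.0 - q))
        return out if out.ndim else float(out)

    quantile = ppf

    def sf(self, g):
        """Tail probability 1/(2g) of an observed p-gain g >= 1.

        This is the p-value attached to a conservative p-gain; only the upper
        branch is meaningful (g below the median never indicates a gain).
        """
        g = np.asarray(g, dtype=float)
        if np.any(g < 1.0):
            raise ValidationError("tail probability is defined for p-gain >= 1")
        out = 0.5 / g
        return out if out.ndim else float(out)

    tail_probability = sf

    def critical_value(self, alpha: float, B: int = 1) -> float:
        """Bonferroni-corrected critical p-gain B/(2·alpha).

        Valid when alpha/B <= 0.5, i.e. when the corrected level sits on the
        1/(2g) tail branch of the distribution.
        """
        self._check_level(alpha, B)
        return B / (2.0 * alpha)

    def critical_value_log10(self, alpha: float, B: int = 1) -> float:
        """log10 of the critical p-gain; safe for B up to 1e12 and beyond."""
        self._check_level(alpha, B)
        return math.log10(B) - math.log10(2.0 * alpha)

    @staticmethod
    def _check_level(alpha: float, B: int):
        if not 0 < alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
        if B < 1 or int(B) != B:
            raise ValidationError(f"B must be a positive integer, got {B}")
        if alpha / B > 0.5:
            raise ValidationError(
                f"alpha/B = {alpha / B:g} > 0.5: the corrected level must fall "
                "on the upper tail branch for the critical value B/(2*alpha)"
            )

    def rvs(self, size: int, rng=None) -> np.ndarray:
        """Draw from the null by brute force: ratio of two independent uniforms."""
        rng = np.random.default_rng(rng)
        u1 = rng.uniform(size=size)
        u2 = rng.uniform(size=size)
        return u1 / u2

    def quantile_table(self, probs) -> "np.ndarray":
        """(prob, quantile, log10 quantile) rows for the requested levels."""
        probs = np.asarray(probs, dtype=float)
        q = self.ppf(probs)
        return np.column_stack([probs, q, np.log10(q)])


_NULL = ConservativePGainNull()


def density(g):
    return _NULL.pdf(g)


def cdf(g):
    return _NULL.cdf(g)


def quantile(q):
    return _NULL.ppf(q)


def tail_probability(g):
    return _NULL.sf(g)


def critical_value(alpha: float, B: int = 1) -> Tuple[float, float]:
    """Critical p-gain B/(2·alpha) as ``(linear, log10)``."""
    return _NULL.critical_value(alpha, B), _NULL.critical_value_log10(alpha, B)


def critical_value_log10(alpha: float, B: int = 1) -> float:
    return _NULL.critical_value_log10(alpha, B)
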