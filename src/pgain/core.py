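"""The p-gain statistic and its building blocks.

A metabolite ratio M1/M2 sometimes associates far more strongly with a trait X
(a SNP dosage or a phenotype) than either concentration alone, because a shared
latent scale — dilution, sample amount, upstream pathway activity — cancels in
the quotient.  The p-gain quantifies that benefit:

    p-gain = min(p(M1|X), p(M2|X)) / p(M1/M2|X)

All p-values and p-gains are carried on the log10 scale throughout.  Observed
p-gains reach 1e66 and beyond in real cohorts, far outside double-precision
ratio arithmetic, so the association test computes log10 p directly from the
log tail of the t-distribution and never exponentiates an intermediate.

Ratios are taken as natural-log differences, log(M1) - log(M2); the regression
p-value is invariant to the log base and to the orientation of the ratio
(log(a/b) = -log(b/a) only flips the slope sign).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import special

from .exceptions import (
    DegenerateInputError,
    InsufficientSamplesError,
    NonPositiveConcentrationError,
    ValidationError,
)

__all__ = [
    "AssociationResult",
    "PGainRecord",
    "log_ratio",
    "associate",
    "compute_pgain",
    "pgain_linear",
    "t_log10_sf_two_sided",
]

_LN10 = np.log(10.0)


def t_log10_sf_two_sided(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    """log10 of the two-sided p-value of a t statistic, safe far below underflow.

    For ``t**2 > df`` the regularized incomplete beta is evaluated in log space
    through its hypergeometric representation

        I_x(a, b) = x^a (1-x)^b / (a B(a, b)) * 2F1(a+b, 1; a+1; x),

    with ``x = df / (df + t^2)``, ``a = df/2``, ``b = 1/2``, so that p-values of
    magnitude 1e-2500 still come back as finite log10 values.  Elsewhere the
    direct tail is accurate and cheaper.  Matches R's
    ``pt(lower.tail=FALSE, log.p=TRUE)`` to ~12 digits.
    """
    t = np.abs(np.asarray(t, dtype=float))
    df = np.asarray(df, dtype=float)
    x = df / (df + t * t)
    a = df / 2.0
    b = 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        # log of one tail via the log-space incomplete beta series
        series = (
            np.log(0.5)
            + a * np.log(x)
            + b * np.log1p(-x)
            - np.log(a)
            - special.betaln(a, b)
            + np.log(special.hyp2f1(a + b, 1.0, a + 1.0, x))
        )
        # direct tail: sf = I_x(a, b) / 2, fine when x >= 1/2
        plain = np.log(0.5 * special.betainc(a, b, x))
    log_sf = np.where(x < 0.5, series, plain)
    # two-sided: p = 2 * sf(|t|)
    return (np.log(2.0) + log_sf) / _LN10


def log_ratio(a: Sequence[float], b: Sequence[float]) -> np.ndarray:
    """Natural-log ratio log(a) - log(b) of two positive concentration vectors.

    Antisymmetric: ``log_ratio(a, b) == -log_ratio(b, a)`` exactly.

    Raises
    ------
    NonPositiveConcentrationError
        If any entry of either vector is non-positive or non-finite; the error
        names the offending sample indices.
    ValidationError
        If the vectors differ in length.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(
            f"concentration vectors differ in shape: {a.shape} vs {b.shape}"
        )
    bad = ~(np.isfinite(a) & np.isfinite(b) & (a > 0) & (b > 0))
    if np.any(bad):
        idx = np.flatnonzero(bad)
        shown = ", ".join(map(str, idx[:10])) + ("…" if idx.size > 10 else "")
        raise NonPositiveConcentrationError(
            f"{idx.size} sample(s) with non-positive or non-finite "
            f"concentrations (indices: {shown})",
            samples=idx.tolist(),
        )
    return np.log(a) - np.log(b)


@dataclass(frozen=True)
class AssociationResult:
    """One trait-quantity linear association.

    Attributes
    ----------
    quantity_name : str
        Label of the dependent quantity (a metabolite or a ratio).
    log10_p : float
        log10 of the two-sided p-value for the trait coefficient; always <= 0,
        -inf only when the fit is exact (p identically zero under the model).
    beta : float
        OLS slope of the quantity on the trait.
    explained_variance : float
        Incremental R² contributed by the trait, in [0, 1].
    n_used : int
        Complete cases entering the fit.
    """

    quantity_name: str
    log10_p: float
    beta: float
    explained_variance: float
    n_used: int


def associate(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Optional[np.ndarray] = None,
    name: str = "y",
) -> AssociationResult:
    """Ordinary least squares of ``y`` on ``x`` (plus optional covariates).

    Complete-case analysis: rows with any non-finite value in ``x``, ``y`` or
    the covariates are dropped.  The p-value of the ``x`` coefficient is
    computed on the log10 scale from the log tail of the t-distribution;
    ``explained_variance`` is the incremental R² of ``x`` over the
    covariate-only model.

    Raises
    ------
    DegenerateInputError
        If ``x`` or ``y`` is constant after filtering.
    InsufficientSamplesError
        If fewer complete cases remain than model parameters + 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != x.size:
            covariates = covariates.T
        if covariates.shape[0] != x.size:
            raise ValidationError("covariate rows do not match sample count")
        keep = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(covariates), axis=1)
    else:
        keep = np.isfinite(x) & np.isfinite(y)

    x = x[keep]
    y = y[keep]
    n = int(x.size)
    k_cov = 0 if covariates is None else covariates.shape[1]
    n_params = 2 + k_cov  # intercept + x + covariates
    if n < n_params + 1:
        raise InsufficientSamplesError(
            f"{n} complete cases for {name!r}; need at least {n_params + 1}"
        )
    if np.ptp(x) == 0:
        raise DegenerateInputError(f"trait is constant over the {n} complete cases")
    if np.ptp(y) == 0:
        raise DegenerateInputError(f"{name!r} is constant over the {n} complete cases")

    df = n - n_params
    if covariates is None:
        # closed-form simple regression: t-test on the slope == correlation test
        xc = x - x.mean()
        yc = y - y.mean()
        sxx = xc @ xc
        sxy = xc @ yc
        syy = yc @ yc
        beta = sxy / sxx
        r2 = (sxy * sxy) / (sxx * syy)
        r2 = min(r2, 1.0)
        rss = syy * (1.0 - r2)
        explained = r2
    else:
        cov = covariates[keep]
        design_full = np.column_stack([np.ones(n), x, cov])
        design_red = np.column_stack([np.ones(n), cov])
        coef, _, rank, _ = np.linalg.lstsq(design_full, y, rcond=None)
        if rank < design_full.shape[1]:
            raise DegenerateInputError(
                "design matrix is rank deficient (collinear trait/covariates)"
            )
        resid = y - design_full @ coef
        rss = resid @ resid
        coef_r, _, _, _ = np.linalg.lstsq(design_red, y, rcond=None)
        resid_r = y - design_red @ coef_r
        rss_r = resid_r @ resid_r
        syy = np.sum((y - y.mean()) ** 2)
        beta = coef[1]
        explained = float(np.clip((rss_r - rss) / syy, 0.0, 1.0))
        xx_inv = np.linalg.inv(design_full.T @ design_full)
        sxx = 1.0 / xx_inv[1, 1]

    if rss <= 0:
        # exact fit: p is identically zero under the model
        log10_p = -np.inf
        tstat = np.inf
    else:
        sigma2 = rss / df
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
        log10_p = float(t_log10_sf_two_sided(tstat, df))
    return AssociationResult(
        quantity_name=name,
        log10_p=min(log10_p, 0.0),
        beta=float(beta),
        explained_variance=float(explained),
        n_used=n,
    )


def compute_pgain(log10_p1: float, log10_p2: float, log10_p_ratio: float) -> float:
    """log10 p-gain from the three log10 p-values.

    ``log10_pgain = min(log10_p1, log10_p2) - log10_p_ratio``; symmetric in the
    first two arguments.  Inputs must be <= 0 (p-values cannot exceed 1).
    """
    for v in (log10_p1, log10_p2, log10_p_ratio):
        if v > 0:
            raise ValidationError(
                f"log10 p-value {v} is positive; p-values must be <= 1"
            )
    return min(log10_p1, log10_p2) - log10_p_ratio


def pgain_linear(log10_pgain: float) -> Tuple[float, bool]:
    """Linear-scale p-gain ``10**log10_pgain`` with an overflow flag.

    Returns ``(value, saturated)``; when the power overflows double precision
    the value saturates at the largest representable float and ``saturated``
    is True.
    """
    max_exp = np.log10(np.finfo(float).max)
    if log10_pgain > max_exp:
        return float(np.finfo(float).max), True
    return float(10.0 ** log10_pgain), False


@dataclass(frozen=True)
class PGainRecord:
    """A tested metabolite pair: three associations and their p-gain."""

    pair: Tuple[str, str]
    res_m1: AssociationResult
    res_m2: AssociationResult
    res_ratio: AssociationResult
    log10_pgain: float
    B: int
    significant: bool

    @property
    def pgain(self) -> float:
        """Linear-scale p-gain, saturated at the double-precision maximum."""
        return pgain_linear(self.log10_pgain)[0]

    @property
    def pgain_saturated(self) -> bool:
        return pgain_linear(self.log10_pgain)[1]
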