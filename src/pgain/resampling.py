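"""Sample-size dependence of the observed p-gain via bootstrap subsampling.

An observed p-gain is not a portable effect size: like a p-value it grows with
the cohort.  Drawing repeated random subsamples (with replacement) of
increasing size from one cohort and recomputing the pair's p-gain at each size
traces that growth; the spread between the quartiles shows the sampling
variability a study of that size should expect.

Defaults (sizes 100, 500, 1000, 1500, 2000; 1500 replicates per size) mirror
the standard experimental design for this diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .cohort import CohortTable
from .core import associate, compute_pgain, log_ratio
from .exceptions import DegenerateInputError, PGainError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["SubsampleSummary", "pgain_vs_sample_size", "DEFAULT_SIZES", "DEFAULT_REPS"]

DEFAULT_SIZES = (100, 500, 1000, 1500, 2000)
DEFAULT_REPS = 1500


@dataclass(frozen=True)
class SubsampleSummary:
    """Quartile summary of log10 p-gain at one subsample size."""

    sample_size: int
    median_log10_pgain: float
    q1_log10_pgain: float
    q3_log10_pgain: float
    n_reps: int
    n_skipped: int = 0

    def __post_init__(self):
        if not (
            self.q1_log10_pgain <= self.median_log10_pgain <= self.q3_log10_pgain
        ):
            raise ValidationError("quartiles out of order")


def _pair_pgain(x, a, b, log_transform_single=True) -> float:
    """One p-gain for a metabolite pair against a trait vector."""
    ratio = log_ratio(a, b)
    ya = np.log(a) if log_transform_single else a
    yb = np.log(b) if log_transform_single else b
    r1 = associate(x, ya, name="m1")
    r2 = associate(x, yb, name="m2")
    rr = associate(x, ratio, name="ratio")
    return compute_pgain(r1.log10_p, r2.log10_p, rr.log10_p)


def pgain_vs_sample_size(
    cohort: CohortTable,
    pair: Tuple[str, str],
    sizes: Sequence[int] = DEFAULT_SIZES,
    n_reps: int = DEFAULT_REPS,
    seed: Optional[int] = None,
    replace: bool = True,
) -> List[SubsampleSummary]:
    """Median/Q1/Q3 of the pair's log10 p-gain across bootstrap sizes.

    For each requested size, draws ``n_reps`` subsamples with replacement from
    the cohort's complete cases for the pair and recomputes the p-gain.
    Replicates whose subsample has a constant trait (or another degeneracy)
    are skipped and counted; more than 10 % skips at any size aborts.

    ``replace=False`` exists for the identity check (a full-size draw without
    replacement reproduces the full-cohort p-gain exactly); quartiles use the
    same type-7 order-statistic interpolation as the copula simulator.
    """
    m1, m2 = pair
    names = set(cohort.metabolite_names)
    if m1 not in names or m2 not in names:
        raise ValidationError(f"pair ({m1}, {m2}) not present in the cohort")
    if any(s < 10 for s in sizes):
        raise ValidationError("every subsample size must be >= 10")
    rng = np.random.default_rng(seed)

    a = cohort.metabolites[m1].to_numpy(dtype=float)
    b = cohort.metabolites[m2].to_numpy(dtype=float)
    x = cohort.trait.to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(x) & (a > 0) & (b > 0)
    n_bad = int(np.sum(~ok))
    if n_bad:
        logger.warning("pair (%s, %s): %d incomplete sample(s) excluded", m1, m2, n_bad)
    a, b, x = a[ok], b[ok], x[ok]
    n_avail = a.size

    summaries = []
    for size in sizes:
        if not replace and size > n_avail:
            raise ValidationError(
                f"size {size} exceeds the {n_avail} available samples "
                "without replacement"
            )
        vals = []
        skipped = 0
        for _ in range(n_reps):
            idx = (
                rng.integers(0, n_avail, size)
                if replace
                else rng.permutation(n_avail)[:size]
            )
            try:
                vals.append(_pair_pgain(x[idx], a[idx], b[idx]))
            except DegenerateInputError as exc:
                skipped += 1
                logger.debug("size %d replicate skipped: %s", size, exc)
        if skipped > 0.1 * n_reps:
            raise PGainError(
                f"{skipped}/{n_reps} replicates degenerate at size {size}; "
                "the cohort is too small or the trait too sparse"
            )
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        summaries.append(
            SubsampleSummary(
                sample_size=int(size),
                median_log10_pgain=float(med),
                q1_log10_pgain=float(q1),
                q3_log10_pgain=float(q3),
                n_reps=n_reps,
                n_skipped=skipped,
            )
        )
    return summaries
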