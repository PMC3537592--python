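"""Trait association scan over all metabolite ratios, Model/Results style.

``PGainScan`` is configured from a :class:`~pgain.cohort.CohortTable`; its
:meth:`~PGainScan.fit` runs, for every unordered metabolite pair, three linear
regressions (each single metabolite and their log-ratio on the trait), forms
the p-gain, and returns a :class:`PGainScanResults` carrying the per-pair
records, the Bonferroni threshold and a summary table.

The number of tests B is the number of ratio hypotheses actually performed —
each unordered pair counted once, since log(a/b) = -log(b/a) makes the two
orientations the same hypothesis and halves the multiple-testing burden.  The
significance threshold on the log10 scale is log10(B / (2·alpha)).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .core import (
    AssociationResult,
    PGainRecord,
    associate,
    compute_pgain,
    log_ratio,
    pgain_linear,
)
from .exceptions import PGainError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["PGainScan", "PGainScanResults", "SkippedPair", "pgain_scan"]


@dataclass(frozen=True)
class SkippedPair:
    pair: Tuple[str, str]
    reason: str


class PGainScan:
    """Association scan model for metabolite ratios against one trait.

    Parameters
    ----------
    cohort : CohortTable
        Sample-aligned concentrations, trait and optional covariates.
    alpha : float
        Significance level in (0, 0.5]; the per-scan threshold is B/(2·alpha).
    pairs : sequence of (str, str), optional
        Restrict the scan to these unordered pairs; default all C(m, 2).
    log_transform_single : bool
        Log-transform single metabolite concentrations before regression
        (default True, matching the log-scale treatment of the ratio).
    """

    def __init__(
        self,
        cohort: CohortTable,
        alpha: float = 0.05,
        pairs: Optional[Sequence[Tuple[str, str]]] = None,
        log_transform_single: bool = True,
    ):
        if not 0 < alpha <= 0.5:
            raise ValidationError(f"alpha must be in (0, 0.5], got {alpha}")
        if len(cohort.metabolite_names) < 2 and pairs is None:
            raise ValidationError("scan needs at least two metabolites")
        self.cohort = cohort
        self.alpha = float(alpha)
        self.log_transform_single = log_transform_single
        names = set(cohort.metabolite_names)
        if pairs is None:
            self.pairs = list(itertools.combinations(cohort.metabolite_names, 2))
        else:
            self.pairs = []
            for m1, m2 in pairs:
                if m1 not in names or m2 not in names:
                    raise ValidationError(f"unknown metabolite in pair ({m1}, {m2})")
                if m1 == m2:
                    raise ValidationError(f"pair ({m1}, {m2}) is degenerate")
                self.pairs.append((m1, m2))

    @classmethod
    def from_dataframe(
        cls,
        metabolites: pd.DataFrame,
        trait: pd.Series,
        covariates: Optional[pd.DataFrame] = None,
        **kwargs,
    ) -> "PGainScan":
        return cls(CohortTable.from_aligned(metabolites, trait, covariates), **kwargs)

    # -- fitting -----------------------------------------------------------

    def _fit_single(self, name: str, cache: dict) -> AssociationResult:
        if name not in cache:
            y = self.cohort.metabolites[name].to_numpy(dtype=float)
            if self.log_transform_single:
                pos = y > 0
                n_bad = int(np.sum(np.isfinite(y) & ~pos))
                y = np.where(pos & np.isfinite(y), y, np.nan)
                if n_bad:
                    logger.warning(
                        "%s: %d non-positive concentration(s) excluded", name, n_bad
                    )
                y = np.log(y)
            cache[name] = associate(
                self.cohort.trait.to_numpy(dtype=float),
                y,
                covariates=self._cov_array(),
                name=name,
            )
        return cache[name]

    def _cov_array(self):
        if self.cohort.covariates is None:
            return None
        return self.cohort.covariates.to_numpy(dtype=float)

    def fit(self) -> "PGainScanResults":
        """Run the scan; per-pair failures become skipped records, not aborts."""
        cache: dict = {}
        fitted: List[Tuple[Tuple[str, str], AssociationResult, AssociationResult, AssociationResult]] = []
        skipped: List[SkippedPair] = []
        x = self.cohort.trait.to_numpy(dtype=float)
        for m1, m2 in self.pairs:
            try:
                a = self.cohort.metabolites[m1].to_numpy(dtype=float)
                b = self.cohort.metabolites[m2].to_numpy(dtype=float)
                ok = np.isfinite(a) & np.isfinite(b) & (a > 0) & (b > 0)
                n_bad = int(np.sum(~ok))
                if n_bad:
                    logger.warning(
                        "pair (%s, %s): %d sample(s) with non-positive or missing "
                        "concentrations excluded pairwise",
                        m1, m2, n_bad,
                    )
                ratio = np.full(a.shape, np.nan)
                ratio[ok] = log_ratio(a[ok], b[ok])
                res_ratio = associate(
                    x, ratio, covariates=self._cov_array(), name=f"{m1}/{m2}"
                )
                res1 = self._fit_single(m1, cache)
                res2 = self._fit_single(m2, cache)
            except PGainError as exc:
                logger.warning("pair (%s, %s) skipped: %s", m1, m2, exc)
                skipped.append(SkippedPair((m1, m2), str(exc)))
                continue
            fitted.append(((m1, m2), res1, res2, res_ratio))

        B = len(fitted)
        if B == 0:
            raise ValidationError(
                "no pair could be tested; all were skipped "
                f"({'; '.join(s.reason for s in skipped[:3])} …)"
            )
        crit_log10 = math.log10(B / (2.0 * self.alpha))
        records = []
        for pair, res1, res2, res_ratio in fitted:
            lg = compute_pgain(res1.log10_p, res2.log10_p, res_ratio.log10_p)
            records.append(
                PGainRecord(
                    pair=pair,
                    res_m1=res1,
                    res_m2=res2,
                    res_ratio=res_ratio,
                    log10_pgain=lg,
                    B=B,
                    significant=lg >= crit_log10,
                )
            )
        records.sort(key=lambda r: (-r.log10_pgain, r.pair))
        logger.info(
            "scan: %d pair(s) tested, %d skipped, B=%d, critical p-gain 10^%.4g",
            B, len(skipped), B, crit_log10,
        )
        return PGainScanResults(
            records=records,
            skipped=skipped,
            alpha=self.alpha,
            B=B,
            critical_log10=crit_log10,
        )


class PGainScanResults:
    """Fitted scan: ordered records, threshold, summary table."""

    def __init__(self, records, skipped, alpha, B, critical_log10):
        self.records: List[PGainRecord] = records
        self.skipped: List[SkippedPair] = skipped
        self.alpha = alpha
        self.B = B
        self.critical_log10 = critical_log10

    @property
    def n_significant(self) -> int:
        return sum(r.significant for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view, one row per tested pair, sorted by descending p-gain."""
        rows = []
        for r in self.records:
            lin, sat = pgain_linear(r.log10_pgain)
            rows.append(
                {
                    "pair_m1": r.pair[0],
                    "pair_m2": r.pair[1],
                    "log10_p_m1": r.res_m1.log10_p,
                    "log10_p_m2": r.res_m2.log10_p,
                    "log10_p_ratio": r.res_ratio.log10_p,
                    "log10_pgain": r.log10_pgain,
                    "pgain_linear": lin,
                    "pgain_saturated": sat,
                    "n_used": r.res_ratio.n_used,
                    "B": r.B,
                    "critical_log10": self.critical_log10,
                    "significant": r.significant,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "p-gain ratio association scan",
            "=" * 64,
            f"pairs tested (B):     {self.B}",
            f"pairs skipped:        {len(self.skipped)}",
            f"alpha:                {self.alpha}",
            f"critical p-gain:      {self.B / (2 * self.alpha):g} "
            f"(log10 = {self.critical_log10:.4f})",
            f"significant pairs:    {self.n_significant}",
            "-" * 64,
        ]
        with pd.option_context("display.width", 120, "display.max_rows", 20):
            lines.append(
                df[
                    ["pair_m1", "pair_m2", "log10_p_ratio", "log10_pgain", "significant"]
                ].to_string(index=False)
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar plot of log10 p-gains against the Bonferroni threshold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.to_frame()
        labels = df["pair_m1"] + "/" + df["pair_m2"]
        ax.bar(labels, df["log10_pgain"], color="steelblue")
        ax.axhline(self.critical_log10, color="firebrick", ls="--",
                   label=f"critical: B/(2α) = {self.B / (2 * self.alpha):g}")
        ax.set_ylabel("log10 p-gain")
        ax.legend()
        ax.tick_params(axis="x", rotation=90)
        return ax


def pgain_scan(
    cohort: CohortTable,
    alpha: float = 0.05,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
    **kwargs,
) -> List[PGainRecord]:
    """Functional wrapper: fit a :class:`PGainScan` and return its records."""
    return PGainScan(cohort, alpha=alpha, pairs=pairs, **kwargs).fit().records
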