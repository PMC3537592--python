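"""Sample-aligned cohort container: metabolite matrix, trait, covariates."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CohortTable:
    """Metabolite concentrations with a per-sample trait, aligned on sample ID.

    ``metabolites`` holds strictly positive concentrations (arbitrary units,
    samples in rows, named columns); ``trait`` is a numeric vector — either a
    continuous phenotype or an additive genotype dosage in [0, 2]; optional
    numeric ``covariates``.  Validation of positivity happens per test in the
    scan (complete-case, pairwise), not at construction: a cohort may carry
    missing values.
    """

    metabolites: pd.DataFrame
    trait: pd.Series
    covariates: Optional[pd.DataFrame] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.metabolites.index.has_duplicates:
            dup = self.metabolites.index[self.metabolites.index.duplicated()][0]
            raise ValidationError(f"duplicate sample ID in metabolite table: {dup!r}")
        if not self.metabolites.index.equals(self.trait.index):
            raise ValidationError("metabolite and trait tables are not sample-aligned")
        if self.covariates is not None and not self.metabolites.index.equals(
            self.covariates.index
        ):
            raise ValidationError("covariate table is not sample-aligned")
        if self.metabolites.shape[1] < 1:
            raise ValidationError("cohort has no metabolite columns")

    @property
    def sample_ids(self) -> pd.Index:
        return self.metabolites.index

    @property
    def n_samples(self) -> int:
        return len(self.metabolites)

    @property
    def metabolite_names(self) -> list:
        return list(self.metabolites.columns)

    @classmethod
    def from_aligned(
        cls,
        metabolites: pd.DataFrame,
        trait: pd.Series,
        covariates: Optional[pd.DataFrame] = None,
    ) -> "CohortTable":
        """Build a cohort from possibly unaligned tables, intersecting on ID.

        Samples missing from any table are dropped with a logged count.
        """
        common = metabolites.index.intersection(trait.index)
        if covariates is not None:
            common = common.intersection(covariates.index)
        if len(common) == 0:
            raise ValidationError("no sample IDs shared across the input tables")
        dropped = len(metabolites) - len(common)
        if dropped:
            logger.info(
                "dropped %d sample(s) absent from the trait/covariate tables", dropped
            )
        cov = covariates.loc[common] if covariates is not None else None
        return cls(
            metabolites=metabolites.loc[common],
            trait=trait.loc[common],
            covariates=cov,
        )

    def subsample(self, indices: np.ndarray) -> "CohortTable":
        """Positional resample (bootstrap support); duplicates allowed."""
        met = self.metabolites.iloc[indices].reset_index(drop=True)
        tr = self.trait.iloc[indices].reset_index(drop=True)
        cov = (
            self.covariates.iloc[indices].reset_index(drop=True)
            if self.covariates is not None
            else None
        )
        return CohortTable(metabolites=met, trait=tr, covariates=cov)
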