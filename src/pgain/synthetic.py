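"""Synthetic cohort generator with known ground truth.

The generator emulates the data situation in which metabolite ratios earn
their keep: two log-normally distributed metabolite concentrations share a
latent log-scale component u (pathway activity, dilution, sample amount) and
a biallelic SNP acts additively on the log concentrations,

    G  ~ Binomial(2, maf)                      (Hardy-Weinberg genotypes)
    u  ~ Normal(0, shared_sd²)
    log M1 = beta1·G + u + e1,   e1 ~ Normal(0, noise_sd1²)
    log M2 = beta2·G + u + e2,   e2 ~ Normal(0, noise_sd2²)

Concentrations are returned on the linear scale (exponentiated) so the scan's
log handling is exercised; the trait is the genotype dosage G.

With opposite-sign effects (beta1 > 0 > beta2) the pair behaves like the
substrate and product of an enzymatic reaction: the genotype pushes the two
concentrations apart while u inflates both, so u cancels in log(M1/M2) and
the ratio association is far stronger than either single metabolite's — the
internal-normalization mechanism that motivates ratio testing.  With all
betas zero the generator is a null cohort for calibration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .exceptions import ValidationError

__all__ = ["GeneratorSpec", "generate_cohort", "expected_log_correlation"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the two-metabolite synthetic cohort.

    Attributes
    ----------
    n : int
        Sample count.
    maf : float
        Minor-allele frequency in (0, 0.5].
    beta1, beta2 : float
        Additive genotype effects on log M1 / log M2 (per allele, log units).
    shared_sd : float
        SD of the latent component common to both log metabolites.
    noise_sd1, noise_sd2 : float
        Residual SDs of the two log metabolites; each metabolite needs
        shared or residual variance > 0.
    seed : int
        Seed for the generator; identical spec + seed gives an identical
        cohort.
    """

    n: int = 1000
    maf: float = 0.3
    beta1: float = 0.25
    beta2: float = -0.25
    shared_sd: float = 1.0
    noise_sd1: float = 0.5
    noise_sd2: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n < 3:
            raise ValidationError("n must be at least 3")
        if not 0 < self.maf <= 0.5:
            raise ValidationError(f"maf must be in (0, 0.5], got {self.maf}")
        for name in ("shared_sd", "noise_sd1", "noise_sd2"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.shared_sd == 0 and (self.noise_sd1 == 0 or self.noise_sd2 == 0):
            raise ValidationError(
                "degenerate spec: each metabolite needs shared or residual "
                "variance"
            )

    def ground_truth(self) -> dict:
        """Generator parameters plus derived quantities, for provenance files."""
        d = asdict(self)
        d["expected_cor_log"] = expected_log_correlation(self)
        d["ratio_effect"] = self.beta1 - self.beta2
        return d


def expected_log_correlation(spec: GeneratorSpec) -> float:
    """Population correlation of (log M1, log M2) at beta1 = beta2 = 0.

    The latent-factor model gives
    cor = shared_sd² / sqrt((shared_sd² + noise_sd1²)(shared_sd² + noise_sd2²)).
    """
    s2 = spec.shared_sd**2
    return float(
        s2 / np.sqrt((s2 + spec.noise_sd1**2) * (s2 + spec.noise_sd2**2))
    )


def generate_cohort(spec: GeneratorSpec, seed: Optional[int] = None) -> CohortTable:
    """Draw one cohort from the spec (``seed`` overrides ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    g = rng.binomial(2, spec.maf, spec.n).astype(float)
    u = rng.normal(0.0, spec.shared_sd, spec.n)
    e1 = rng.normal(0.0, spec.noise_sd1, spec.n)
    e2 = rng.normal(0.0, spec.noise_sd2, spec.n)
    log_m1 = spec.beta1 * g + u + e1
    log_m2 = spec.beta2 * g + u + e2
    ids = pd.Index([f"S{i:05d}" for i in range(spec.n)], name="sample_id")
    metabolites = pd.DataFrame(
        {"M1": np.exp(log_m1), "M2": np.exp(log_m2)}, index=ids
    )
    trait = pd.Series(g, index=ids, name="trait")
    return CohortTable(
        metabolites=metabolites,
        trait=trait,
        extras={"ground_truth": spec.ground_truth()},
    )
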