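import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

from pgain import CohortTable, GeneratorSpec, generate_cohort

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def planted_cohort():
    """Substrate/product pair: opposite-sign genotype effects on the logs."""
    return generate_cohort(GeneratorSpec(n=1000, seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """Independent metabolites, no genotype effect anywhere."""
    return generate_cohort(
        GeneratorSpec(n=1000, beta1=0.0, beta2=0.0, shared_sd=0.0, seed=12)
    )


@pytest.fixture()
def three_metabolite_cohort(planted_cohort):
    """The planted pair plus one unrelated metabolite."""
    rng = np.random.default_rng(7)
    met = planted_cohort.metabolites.copy()
    met["M3"] = np.exp(rng.normal(size=len(met)))
    return CohortTable(metabolites=met, trait=planted_cohort.trait.copy())


@pytest.fixture()
def cohort_files(tmp_path, planted_cohort):
    """The planted cohort written out as TSV inputs."""
    met_path = tmp_path / "metabolites.tsv"
    trait_path = tmp_path / "trait.tsv"
    planted_cohort.metabolites.to_csv(met_path, sep="\t")
    planted_cohort.trait.to_frame().to_csv(trait_path, sep="\t")
    return met_path, trait_path
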