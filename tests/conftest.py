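import numpy as np
import pandas as pd
import pytest

from genebankgp import GenotypeMatrix, SimulationConfig, TraitBLUEs, simulate_genotypes


def make_blues(values, trait="trait", ses=None, n_years=2.0) -> TraitBLUEs:
    """Wrap a mapping/Series of accession -> value as TraitBLUEs."""
    est = pd.Series(values, dtype=float)
    if ses is None:
        ses = pd.Series(0.1, index=est.index)
    return TraitBLUEs(trait=trait, estimates=est, standard_errors=ses, n_years_mean=n_years)


@pytest.fixture
def make_blues_fn():
    return make_blues


@pytest.fixture(scope="session")
def small_genotypes() -> GenotypeMatrix:
    """60 accessions x 120 imputed markers, outbred coding for kernel tests."""
    cfg = SimulationConfig(
        n_accessions=60, n_markers=120, maf_range=(0.1, 0.5), inbreeding=0.0, seed=11
    )
    gm = simulate_genotypes(cfg)
    gm.allele_freqs = gm.codes.mean(axis=0) / 2.0
    return gm


@pytest.fixture(scope="session")
def trial_config() -> SimulationConfig:
    """Fully replicated three-year design used by the curation tests."""
    return SimulationConfig(
        n_accessions=120,
        n_markers=200,
        n_years=3,
        year_plan={"Y1": 1.0, "Y2": 1.0, "Y3": 1.0},
        year_error_sds=[0.8, 1.0, 1.2],
        heritability_target=0.5,
        outlier_rate=0.0,
        seed=7,
    )


def centered(gm: GenotypeMatrix) -> np.ndarray:
    p = gm.allele_freqs if gm.allele_freqs is not None else gm.codes.mean(axis=0) / 2.0
    return gm.codes - 2.0 * p
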