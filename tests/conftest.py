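"""Shared fixtures: small synthetic panels generated at test time."""

import numpy as np
import pandas as pd
import pytest

from popmeth import methylome_core as mc
from popmeth.synthetic_data import SimulationConfig, simulate_dataset


def small_config(**overrides) -> SimulationConfig:
    """A compact panel: 2 x 1 Mb genome, 10 planted DMRs per comparison."""
    base = dict(
        n_chroms=2,
        chrom_length=1_000_000,
        n_per_pop=8,
        n_sites_per_context=2_000,
        n_snps=2_000,
        n_planted_dmrs=10,
        n_sweeps=2,
        n_meqtl_dmrs=1,
        n_coupled_genes=6,
        n_genes=60,
        seed=7,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config())


def build_matrix(dataset, min_reads=3, min_fraction_present=0.7):
    pooled = {
        acc: mc.filter_coverage(dataset.accession_records(acc), min_reads)
        for acc in dataset.accessions
    }
    pops = dict(
        zip(dataset.sample_sheet["accession"], dataset.sample_sheet["population"])
    )
    return mc.build_methylation_matrix(
        pooled,
        populations=pops,
        min_fraction_present=min_fraction_present,
        min_reads=min_reads,
    )


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    return build_matrix(small_dataset)


@pytest.fixture(scope="session")
def small_populations(small_dataset):
    return dict(
        zip(
            small_dataset.sample_sheet["accession"],
            small_dataset.sample_sheet["population"],
        )
    )


def matrix_from_levels(levels: np.ndarray, sites: pd.DataFrame, accessions, depth=100):
    """Build a MethylationMatrix with exact levels via counts m = level * depth."""
    total = np.full(levels.shape, depth, dtype=np.int64)
    meth = np.round(levels * depth).astype(np.int64)
    return mc.MethylationMatrix(
        sites=sites.reset_index(drop=True),
        meth=meth,
        total=total,
        accessions=list(accessions),
        min_reads=3,
    )
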