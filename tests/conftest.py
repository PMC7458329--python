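from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from snpforge.matrix import GenotypeMatrix
from snpforge import synthetic_data as sd


def make_matrix(calls: dict[str, list[int]], populations: dict[str, str],
                regions: dict[str, str] | None = None) -> GenotypeMatrix:
    """Small-matrix builder: calls maps sample -> genotype codes."""
    frame = pd.DataFrame.from_dict(calls, orient="index")
    frame.columns = [f"L{i + 1}" for i in range(frame.shape[1])]
    samples = pd.DataFrame(
        {
            "population": pd.Series(populations),
            "region": pd.Series(regions) if regions else "R1",
            "duplicate_of": pd.Series([pd.NA] * len(frame), index=frame.index, dtype=object),
            "dqc": 0.99,
        }
    ).loc[frame.index]
    return GenotypeMatrix(frame, samples)


@pytest.fixture(scope="session")
def hier_matrix():
    cfg = sd.PopulationSimConfig(
        n_regions=2,
        pops_per_region=[2, 3],
        n_per_pop=10,
        n_loci=300,
        theta_region=0.2,
        theta_pop=0.05,
        seed=42,
    )
    matrix, truth = sd.simulate_hierarchical_genotypes(cfg)
    return matrix, truth


@pytest.fixture(scope="session")
def discovery_sim():
    cfg = sd.DiscoverySimConfig(
        n_contigs=6,
        contig_length=4000,
        snp_rate=0.004,
        indel_rate=0.0006,
        cluster_fraction=0.2,
        lcr_fraction=0.004,
        haploid_het_fraction=0.1,
        lowconf_fraction=0.05,
        homopolymer_fraction=0.05,
        short_flank_fraction=0.02,
        excluded_contig_fraction=0.2,
        seed=7,
    )
    return sd.simulate_discovery_dataset(cfg)


@pytest.fixture(scope="session")
def random_reference():
    rng = np.random.default_rng(123)
    return {
        f"ctg{i}": "".join(rng.choice(list("ACGT"), size=400)) for i in range(4)
    }
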