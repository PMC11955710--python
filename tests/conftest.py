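import numpy as np
import pandas as pd
import pytest

from poolpop.config import SimulationConfig, TraitConfig
from poolpop.poolfreq import AlleleFrequencyMatrix


def make_loci(n, chrom="chr1", start=1000, step=1000):
    pos = np.arange(start, start + n * step, step)
    return pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"})


def make_afm(values, stage="imputed", populations=None):
    values = np.asarray(values, dtype=float)
    n_pops, n_loci = values.shape
    pops = populations or [f"P{i:03d}" for i in range(1, n_pops + 1)]
    return AlleleFrequencyMatrix(pops, make_loci(n_loci), values, stage=stage)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    return SimulationConfig(
        seed=7,
        n_clusters=3,
        pops_per_cluster=[4, 4, 4],
        n_loci=120,
        n_adaptive=6,
        trait_config={
            "biomass": TraitConfig(
                sigma2_p=1.0,
                sigma2_e=0.5,
                n_locations=1,
                n_years=2,
                n_seasons=2,
                n_reps=2,
                n_rows=4,
                n_cols=3,
            )
        },
    )


@pytest.fixture
def random_afm(rng):
    return make_afm(rng.uniform(0.05, 0.95, size=(8, 40)))
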