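import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from clgkit.model import GeneMap
from clgkit.simulate import SimulationConfig, simulate

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A light simulated dataset shared by unit tests (4 CLGs, 1 outgroup
    fusion, 2 ingroup species)."""
    cfg = SimulationConfig(
        n_clgs=4,
        genes_per_clg=120,
        ingroup_names=("spA", "spB"),
        lineage_scramble_inversions=120,
        outgroup_fusions=1,
        stem_fusions=2,
        stem_mixing_inversions=10,
        seed=11,
    )
    return simulate(cfg)


def make_gene_map(species, chrom_sizes, prefix="g"):
    """GeneMap with the given {chromosome: n_genes} and evenly spaced bp."""
    rows = []
    counter = 0
    for chrom, n in chrom_sizes.items():
        for i in range(n):
            rows.append((f"{prefix}{counter:05d}", chrom, (i + 1) * 100))
            counter += 1
    return GeneMap.from_rows(species, rows)
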