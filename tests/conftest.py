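import numpy as np
import pytest

from morphopop.datamodel import MISSING, GenotypeMatrix, TraitMatrix
from morphopop.simulate import PopulationDesign, SimDesign, simulate_genotypes


def make_design(
    n_pops=4, n=20, F=0.15, n_loci=10, seed=0, clonality=0.0,
    null_freq=None, clusters=None, cluster_F=None, null_drift=False,
):
    pops = [
        PopulationDesign(
            name=f"P{i + 1}", species="sp", management="wild", n=n, F=F,
            clonality=clonality,
            cluster=None if clusters is None else clusters[i],
        )
        for i in range(n_pops)
    ]
    return SimDesign(
        populations=pops, n_loci=n_loci, seed=seed,
        cluster_F=cluster_F or {}, null_freq=null_freq, null_drift=null_drift,
    )


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    """Two populations, two loci, hand-built (one missing genotype)."""
    alleles = np.array(
        [
            [[120, 120], [200, 202]],
            [[120, 124], [200, 200]],
            [[124, 124], [MISSING, MISSING]],
            [[120, 124], [202, 202]],
        ]
    )
    return GenotypeMatrix(
        individual_ids=["a1", "a2", "b1", "b2"],
        population_ids=["A", "A", "B", "B"],
        loci=["L1", "L2"],
        alleles=alleles,
    )


@pytest.fixture
def sim_genotypes() -> GenotypeMatrix:
    return simulate_genotypes(make_design(seed=11))


@pytest.fixture
def small_traits() -> TraitMatrix:
    rng = np.random.default_rng(5)
    vals = np.column_stack(
        [rng.normal(10, 2, 12), rng.normal(5, 1, 12), rng.normal(50, 8, 12)]
    )
    return TraitMatrix(
        individual_ids=[f"i{k}" for k in range(12)],
        population_ids=["A"] * 6 + ["B"] * 6,
        characters=["len", "width", "height"],
        values=vals,
        management={"A": "wild", "B": "cultivated"},
    )
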