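import numpy as np
import pytest

from cycletx import ExpressionTimeCourse, SpeciesTree
from cycletx.periodicity import PeriodicityParams

# caterpillar holozoan-style tree: focal leaf Cowc, internal node labels are
# the nested ancestors that carry the age classes
CATERPILLAR_NEWICK = (
    "(((((Cowc,Mvib)Filozoa,Mbre)Holozoa,Scer)Opisthokonta,Ddis)Unikonta,Atha)"
    "Paneukaryotic;"
)

NODE_AGES = {
    "Cowc": 0,
    "Filozoa": 1,
    "Holozoa": 2,
    "Opisthokonta": 3,
    "Unikonta": 4,
    "Paneukaryotic": 5,
}


@pytest.fixture
def species_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(CATERPILLAR_NEWICK, focal_species="Cowc")


@pytest.fixture
def node_ages() -> dict:
    return dict(NODE_AGES)


@pytest.fixture
def fast_params() -> PeriodicityParams:
    """Permutation settings small enough for unit tests."""
    return PeriodicityParams(n_permutations=2000, seed=7)


@pytest.fixture
def exact_params() -> PeriodicityParams:
    """Short-series parameters that trigger the exact n! null."""
    return PeriodicityParams(period_grid_samples=(4, 5, 6), rain_period_samples=6,
                             method="exact", seed=7)


def make_timecourse(values, times=None, gene_ids=None, **kw) -> ExpressionTimeCourse:
    values = np.asarray(values, dtype=float)
    if times is None:
        times = 2.0 + 0.75 * np.arange(values.shape[1])
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionTimeCourse(gene_ids=gene_ids, times=times, values=values, **kw)


@pytest.fixture
def tiny_tc() -> ExpressionTimeCourse:
    return make_timecourse([[1.0, 2.0, 3.0, 2.0], [5.0, 4.0, 3.0, 4.0]])
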