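import numpy as np
import pytest

from fusewalk.enrichment import RankedGeneList
from fusewalk.propagation import GeneNetwork
from fusewalk.synthetic import ScenarioParams, generate_scenario, worked_example_fixture


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_fixture()


@pytest.fixture(scope="session")
def scenario():
    """Standard planted-module scenario, shared across test modules."""
    return generate_scenario(ScenarioParams(), seed=11)


@pytest.fixture(scope="session")
def small_scenario():
    """Cheaper variant for tests that re-run the pipeline repeatedly."""
    return generate_scenario(
        ScenarioParams(n_genes=200, module_size=25, n_decoy_pathways=20,
                       n_samples_per_group=5, decoy_size_min=10, decoy_size_max=30),
        seed=5,
    )


@pytest.fixture
def ten_gene_list():
    genes = [f"g{i:02d}" for i in range(10)]
    scores = np.array([10.0, 9.0, 8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
    return RankedGeneList(genes=genes, scores=scores)


@pytest.fixture
def path_network():
    """3-node path a-b-c."""
    return GeneNetwork(["a", "b", "c"], [("a", "b"), ("b", "c")])


def brute_force_es(genes, scores, members, weight):
    """Independent running-sum oracle: plain Python left-to-right scan."""
    members = set(members) & set(genes)
    n = len(genes)
    nh = len(members)
    wmap = {g: abs(s) ** weight for g, s in zip(genes, scores)}
    total = sum(wmap[g] for g in genes if g in members)
    miss = 1.0 / (n - nh)
    running = 0.0
    best = 0.0
    for g in genes:
        if g in members:
            running += (wmap[g] / total) if total > 0 else 1.0 / nh
        else:
            running -= miss
        if abs(running) > abs(best):
            best = running
    return best
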