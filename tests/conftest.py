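import numpy as np
import pytest

from coocnet.io_model import AbundanceTable, CooccurrenceNetwork
from coocnet.synthetic import PlantedDesign, PlantedEdge, generate_dataset


def make_network(env: str, edges, signs=None, rhos=None) -> CooccurrenceNetwork:
    """Tiny attributed network builder used across test modules."""
    net = CooccurrenceNetwork(environment=env)
    for a, b in edges:
        for v in (a, b):
            if v not in net.graph:
                net.add_vertex(v)
        sign = (signs or {}).get((a, b), 1)
        rho = (rhos or {}).get((a, b), 0.8 * sign)
        net.add_edge(a, b, sign=sign, rho=rho, bc_sim=0.7, p_spearman=0.01,
                     p_bc=0.02, p_merged=0.001, p_adjusted=0.01)
    return net


@pytest.fixture
def tiny_table() -> AbundanceTable:
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(6, 10))
    env = {f"S{j}": ("soil" if j < 5 else "saline water") for j in range(10)}
    return AbundanceTable(
        [f"E{i}" for i in range(6)], [f"S{j}" for j in range(10)], counts, env
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """One-environment table with 10 planted edges (7 positive, 3 negative)."""
    envs = frozenset(["soil"])
    planted = [
        PlantedEdge(f"ESV{2 * k:02d}", f"ESV{2 * k + 1:02d}",
                    0.9 if k < 7 else -0.9, envs)
        for k in range(10)
    ]
    design = PlantedDesign(
        n_environments=1, samples_per_environment=200, n_esvs=60,
        planted_edges=planted, seed=101,
    )
    table, truth = generate_dataset(design)
    return design, table, truth
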