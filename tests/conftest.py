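import itertools

import numpy as np
import pytest

from rehabgait.network import ConditionalTable, NetworkModel, NodeSpec


def random_network(seed: int, n_nodes: int = 8, max_parents: int = 3
                   ) -> NetworkModel:
    """A random small DAG with random CPTs over 2-3-state nodes.

    Node ids are V0..Vk in topological order; edges only point forward, so
    the result is acyclic by construction.  Used to cross-check the two
    inference engines against each other.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_nodes + 1))
    cards = rng.integers(2, 4, size=n)
    ids = [f"V{i}" for i in range(n)]
    nodes = []
    for i, nid in enumerate(ids):
        role = "observation_motion" if cards[i] == 2 else "goal"
        states = tuple(f"s{k}" for k in range(cards[i]))
        nodes.append(NodeSpec(nid, nid, role, states))
    edges, tables, priors = [], {}, {}
    for i, nid in enumerate(ids):
        k_par = int(rng.integers(0, min(i, max_parents) + 1))
        parents = sorted(rng.choice(i, size=k_par, replace=False).tolist()) \
            if k_par else []
        parent_ids = tuple(ids[p] for p in parents)
        edges += [(p, nid) for p in parent_ids]
        if not parent_ids:
            vec = rng.dirichlet(np.ones(cards[i]))
            priors[nid] = vec
        else:
            rows = {}
            for cfg in itertools.product(
                    *(range(cards[p]) for p in parents)):
                rows[cfg] = tuple(rng.dirichlet(np.ones(cards[i])))
            tables[nid] = ConditionalTable(nid, parent_ids, rows)
    return NetworkModel(nodes, edges, tables, priors)


def random_evidence(model: NetworkModel, seed: int, p_observe: float = 0.4
                    ) -> dict[str, int]:
    rng = np.random.default_rng(seed + 1)
    out = {}
    for nid in model.nodes:
        if rng.random() < p_observe:
            out[nid] = int(rng.integers(0, model.card(nid)))
    # Keep at least one node unobserved so there is something to query.
    if len(out) == len(model.nodes):
        out.pop(next(iter(out)))
    return out


@pytest.fixture(scope="session")
def default_model():
    from rehabgait.network import build_rehab_network
    return build_rehab_network()


@pytest.fixture(scope="session")
def rom_table():
    from rehabgait.fixtures import load_rom_table
    return load_rom_table()


@pytest.fixture(scope="session")
def table7_rows():
    from rehabgait.fixtures import load_calibration_rows
    return load_calibration_rows("table7")
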