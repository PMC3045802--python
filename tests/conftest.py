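import numpy as np
import pandas as pd
import pytest

import genevote as gv


def make_network(ppi=(), metabolic=(), regulatory=()):
    """Assemble a network from bare (source, target) pairs per layer."""
    return gv.assemble_network(
        [gv.InteractionRecord.create(u, v, "ppi") for u, v in ppi],
        [gv.InteractionRecord(u, v, "metabolic") for u, v in metabolic],
        [gv.InteractionRecord(u, v, "regulatory") for u, v in regulatory],
    )


def random_layered_network(rng, max_nodes=8):
    """A random small multi-layer network for oracle comparisons."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    layers = {}
    for layer, p in (("ppi", 0.3), ("metabolic", 0.15), ("regulatory", 0.15)):
        edges = []
        for i in range(n):
            for j in range(n):
                if i != j and rng.random() < p:
                    if layer == "ppi" and i > j:
                        continue
                    edges.append((nodes[i], nodes[j]))
        layers[layer] = edges
    net = make_network(
        ppi=layers["ppi"], metabolic=layers["metabolic"], regulatory=layers["regulatory"]
    )
    net.genes.update(nodes)
    return net


def combined_directed_edges(net):
    edges = set()
    for e in net.edges:
        edges.add((e.source, e.target))
        if e.layer == "ppi":
            edges.add((e.target, e.source))
    return edges


def random_matrix(rng, n=60):
    """A random but structurally valid 24-column feature matrix."""
    genes = [f"G{i:04d}" for i in range(n)]
    data = {}
    for col in gv.TOPOLOGY_COLUMNS:
        if col == "c":
            data[col] = rng.random(n)
        elif col == "identicalness":
            data[col] = rng.integers(1, 4, n).astype(float)
        elif col in ("cent", "inbet", "inbetppi", "inbetmet", "inbetreg"):
            data[col] = rng.exponential(2.0, n)
        else:
            data[col] = rng.poisson(3.0, n).astype(float)
    data["numtissuesexp"] = rng.integers(0, 33, n).astype(float)
    data["avegexptec"] = np.where(data["numtissuesexp"] > 0, rng.exponential(20, n), 0.0)
    for col in gv.LOCALIZATION_CATEGORIES:
        data[col] = (rng.random(n) < 0.3).astype(float)
    frame = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    frame = frame[list(gv.FEATURE_COLUMNS)]
    # repair the localization invariant: Unknown excludes the rest
    unknown = frame["Unknown"] == 1
    frame.loc[unknown, list(gv.LOCALIZATION_CATEGORIES)] = 0.0
    frame.loc[unknown, "Unknown"] = 1.0
    none_set = frame[list(gv.LOCALIZATION_CATEGORIES)].sum(axis=1) == 0
    frame.loc[none_set, "Unknown"] = 1.0
    return frame


@pytest.fixture(scope="session")
def fast_config():
    """A one-member ensemble for unit tests where speed matters more than
    the full roster."""
    from sklearn.tree import DecisionTreeClassifier

    return gv.EnsembleConfig(
        members=(("tree", DecisionTreeClassifier(min_samples_leaf=4)),),
        bags_per_member=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study():
    """A small morbidity-flavored synthetic study shared across tests."""
    spec = gv.morbidity_like(n_genes=500, prevalence=0.2)
    matrix, positives = gv.generate_study(spec)
    return spec, matrix, positives
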