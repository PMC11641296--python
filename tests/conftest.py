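import numpy as np
import pytest

from hydrobind.featurize import EdgeFeature
from hydrobind.fixtures import FixtureSpec, make_complex
from hydrobind.graph import ComplexGraph
from hydrobind.structures_io import Atom, extract_pocket


@pytest.fixture(scope="session")
def toy_complex():
    """Pocket-extracted synthetic complex with two bridge waters."""
    complex_ = make_complex(FixtureSpec(n_bridge_waters=2, n_decoy_waters=2, seed=11))
    return extract_pocket(complex_, 10.0)


@pytest.fixture(scope="session")
def toy_graphs(toy_complex):
    import warnings

    from hydrobind.graph import build_graph

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            "G_A": build_graph(toy_complex, "G_A"),
            "G_B": build_graph(toy_complex, "G_B"),
            "G_C": build_graph(toy_complex, "G_C"),
        }


def make_random_graph(n: int, p: float, seed: int) -> ComplexGraph:
    """Random ligand-only graph used for structural-encoding oracles."""
    rng = np.random.default_rng(seed)
    atoms = [
        Atom(serial=i + 1, element="C", coords=rng.normal(size=3),
             residue_name="LIG", role="ligand")
        for i in range(n)
    ]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                d = float(np.linalg.norm(atoms[i].coords - atoms[j].coords))
                edges.append((i, j, EdgeFeature(distance=d, pair_type="LL")))
    return ComplexGraph(
        atoms=atoms,
        node_features=np.zeros((n, 58)),
        edges=edges,
        variant="G_A",
        water_threshold_T=6.0,
        base_cutoff=6.0,
    )


def permute_graph(g: ComplexGraph, perm: np.ndarray) -> ComplexGraph:
    inv = np.argsort(perm)
    return ComplexGraph(
        atoms=[g.atoms[i] for i in perm],
        node_features=g.node_features[perm],
        edges=sorted(
            (min(inv[i], inv[j]), max(inv[i], inv[j]), f) for i, j, f in g.edges
        ),
        variant=g.variant,
        water_threshold_T=g.water_threshold_T,
        base_cutoff=g.base_cutoff,
    )
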