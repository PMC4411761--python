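import numpy as np
import pytest

from alphapore import MembraneSlab, analyze, make_tube
from alphapore.endpoints import select_endpoints
from alphapore.model_io import Structure, WeightedAtom
from alphapore.transmembrane import classify_boundary, extract_tm_pores, rank_tm_pores

#: membrane slab used for the synthetic tube (z in [0, 40]; the membrane
#: spans the middle so the two polar openings fall on opposite sides)
TUBE_SLAB = MembraneSlab(10.0, 30.0)


def structure_from_points(P, radii, id="test") -> Structure:
    P = np.asarray(P, float)
    radii = np.broadcast_to(np.asarray(radii, float), (len(P),))
    atoms = [
        WeightedAtom(i + 1, "C", "C", "ALA", i + 1, "A", P[i], float(radii[i]))
        for i in range(len(P))
    ]
    return Structure(atoms, id=id)


def random_structure(n, seed, weighted=True, extent=10.0):
    rng = np.random.default_rng(seed)
    P = rng.uniform(0, extent, size=(n, 3))
    r = rng.uniform(0.5, 1.5, size=n) if weighted else np.full(n, 1e-6)
    return structure_from_points(P, r, id=f"rand-{n}-{seed}")


@pytest.fixture(scope="session")
def tube_analysis():
    """Default synthetic tube, analysed once for the whole session."""
    structure = make_tube(seed=1)
    an = analyze(structure)
    return an


@pytest.fixture(scope="session")
def tube_endpoints(tube_analysis):
    return select_endpoints(tube_analysis.network, k=10)


@pytest.fixture(scope="session")
def tube_tm_pores(tube_analysis, tube_endpoints):
    cls = classify_boundary(tube_endpoints, tube_analysis.network, TUBE_SLAB)
    return rank_tm_pores(extract_tm_pores(tube_analysis.network, cls))


@pytest.fixture(scope="session")
def tube_top_pore(tube_tm_pores):
    return tube_tm_pores[0]
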