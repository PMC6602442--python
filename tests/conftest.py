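import numpy as np
import pytest

from refine2lite.fixtures import (
    make_ideal_helix,
    make_refinement_case,
    make_two_helix_bundle,
    perturb_structure,
)


@pytest.fixture(scope="session")
def helix20():
    return make_ideal_helix(20)


@pytest.fixture(scope="session")
def bundle():
    return make_two_helix_bundle(14, 3)


@pytest.fixture(scope="session")
def case40():
    """One shared synthetic refinement case (40 residues, 2.5 A start)."""
    return make_refinement_case(40, 2.5, seed=0)


@pytest.fixture(scope="session")
def decoy_pair():
    """(perturbed, reference) 8-residue pair for small-toy metric oracles."""
    ref = make_ideal_helix(8)
    return perturb_structure(ref, 2.0, seed=5), ref


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_chain(n, seed, compact=True):
    """A random-torsion backbone used across geometry/energy tests."""
    from refine2lite.geometry import TorsionSeries, rebuild_backbone_from_torsions

    rng = np.random.default_rng(seed)
    if compact:
        phi = np.concatenate([[np.nan], rng.uniform(-150, -40, n - 1)])
        psi = np.concatenate([rng.uniform(-70, 150, n - 1), [np.nan]])
    else:
        phi = np.concatenate([[np.nan], rng.uniform(-180, 180, n - 1)])
        psi = np.concatenate([rng.uniform(-180, 180, n - 1), [np.nan]])
    om = np.concatenate([np.full(n - 1, 180.0), [np.nan]])
    anchor = np.array([[0, 0, 0], [1.458, 0, 0], [2.0, 1.4, 0.0]])
    return rebuild_backbone_from_torsions(TorsionSeries(phi, psi, om), anchor)
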