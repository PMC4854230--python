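"""Shared fixtures: synthetic structures and their simulated target maps.

Everything is generated at test time from the synthetic_fixtures module;
nothing is read from disk.
"""
import numpy as np
import pytest

from flexfit import FixtureSpec, make_fixture, simulate_density

RESOLUTION = 3.0
SPACING = 1.0


@pytest.fixture(scope="session")
def hlh():
    """Packed helix-loop-helix hairpin: (spec, structure, annotation)."""
    spec = FixtureSpec(kind="helix_loop_helix")
    structure, annotation = make_fixture(spec)
    return spec, structure, annotation


@pytest.fixture(scope="session")
def hlh_map(hlh):
    _, structure, _ = hlh
    return simulate_density(structure, RESOLUTION, SPACING)


@pytest.fixture(scope="session")
def hinge():
    """Two hairpin domains joined by an extended linker."""
    spec = FixtureSpec(kind="two_domain_hinge")
    structure, annotation = make_fixture(spec)
    return spec, structure, annotation


@pytest.fixture(scope="session")
def hinge_map(hinge):
    _, structure, _ = hinge
    return simulate_density(structure, RESOLUTION, SPACING)


@pytest.fixture(scope="session")
def helix20():
    spec = FixtureSpec(kind="helix", helix_len=20)
    structure, annotation = make_fixture(spec)
    return spec, structure, annotation


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
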