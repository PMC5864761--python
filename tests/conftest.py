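import numpy as np
import pytest

from dualmode import synthetic_data as synth
from dualmode.cg_model import CGTopology
from dualmode.contact_map import native_contacts


@pytest.fixture(scope="session")
def helix12():
    return synth.make_helix(12)


@pytest.fixture(scope="session")
def helix20():
    return synth.make_helix(20)


@pytest.fixture(scope="session")
def hairpin():
    return synth.make_hairpin(8)


@pytest.fixture(scope="session")
def two_body():
    return synth.make_two_body_complex()


@pytest.fixture(scope="session")
def doc_like_pair():
    """A 56-residue chain and a copy rotated 174 deg about a known axis,
    mimicking the two binding-mode poses of a dockerin."""
    base = synth.make_helix(56)
    return synth.make_rotated_pair(base, axis=[0.3, 0.2, 0.9], angle_deg=174.0, seed=7)


@pytest.fixture(scope="session")
def wt_landscapes():
    """Four-replica two-basin landscape emulating the tailless wild type."""
    spec = synth.LandscapeSpec(basins=synth.DEFAULT_BASINS, replicas=4, jitter=1.0, seed=42)
    return synth.make_landscape(spec)


def make_two_bead_contact(r_nat: float = 3.8) -> CGTopology:
    """Minimal topology: two beads joined by one interface contact."""
    sigma = r_nat / 2 ** (1 / 6)
    return CGTopology(
        positions=np.array([[0.0, 0.0, 0.0], [r_nat, 0.0, 0.0]]),
        chain_of=np.array([0, 1]),
        bonds=np.zeros((0, 2), int),
        bond_lengths=np.zeros(0),
        contacts=np.array([[0, 1]]),
        contact_sigma=np.array([sigma]),
        contact_class=["interface"],
        chirality_quads=np.zeros((0, 4), int),
        chirality_native=np.zeros(0),
    )


@pytest.fixture()
def two_bead_contact():
    return make_two_bead_contact()
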