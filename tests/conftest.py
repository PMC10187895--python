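import numpy as np
import pytest

from termfa.genome import CLOCKWISE, COUNTERCLOCKWISE, Locus, TerSite, build_map
from termfa.simulate import default_map, simulate_control


@pytest.fixture
def toy_map():
    """1 Mb toy circle: oriC at 0, TerA blocks cw at 400 kb, TerB blocks ccw at 600 kb."""
    return build_map(
        length=1_000_000,
        oriC=0,
        ter_sites=[
            TerSite("TerA", 400_000, CLOCKWISE),
            TerSite("TerB", 600_000, COUNTERCLOCKWISE),
        ],
        loci=[Locus("ydcM", 520_000), Locus("lepA", 800_000)],
    )


@pytest.fixture(scope="session")
def ecoli_map():
    """The canonical synthetic E. coli-like chromosome used by scenarios."""
    return default_map()


@pytest.fixture(scope="session")
def control_2000(ecoli_map):
    """Stationary-phase control track on a 2000-window grid."""
    return simulate_control(ecoli_map, 2000, depth=100.0, seed=991)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
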