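import numpy as np
import pytest

from hscompare import scene as sc
from hscompare.chromophores import ChromophoreSpectrum, synthetic_chromophore_library


@pytest.fixture(scope="session")
def library():
    """Bundled synthetic chromophore tables (mu_a, cm^-1)."""
    return synthetic_chromophore_library()


@pytest.fixture(scope="session")
def default_scene():
    """One default two-tissue phantom, shared read-only across tests."""
    return sc.generate_phantom(seed=42)


@pytest.fixture(scope="session")
def noiseless_captures(default_scene):
    """Noiseless, laser-off, identity-crosstalk captures of the phantom."""
    snap_spec = sc.snapshot_camera(24, 30)
    line_spec = sc.linescan_camera(line_length=default_scene.height)
    snap = sc.simulate_snapshot_capture(
        default_scene, snap_spec, sc.NoiseModel(seed=0), np.eye(25))
    line = sc.simulate_linescan_capture(
        default_scene, line_spec, sc.NoiseModel(seed=0, dark_level=400.0))
    return snap, line


def flat_mu_a_table(value: float, name: str = "flat") -> ChromophoreSpectrum:
    """Wavelength-flat absorption table covering the phantom grid."""
    wl = np.arange(350.0, 1020.0, 1.0)
    return ChromophoreSpectrum(name, wl, np.full(wl.size, value))


@pytest.fixture
def clean_geometry():
    """Phantom geometry with every stochastic/extra absorption term off."""
    return sc.PhantomGeometry(
        compositions={"healthy": {}, "pathological": {}, "background": {}},
        flat_mu_a={"healthy": 0.0, "pathological": 0.0, "background": 0.0},
        heterogeneity=0.0,
        path_length_jitter=0.0,
        ring_mu_a=0.0,
        disk_radius=10,
        ring_width=2,
    )
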