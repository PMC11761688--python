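import numpy as np
import pytest

from paintkit import sim


@pytest.fixture(scope="session")
def clutch_scene():
    """Small static clustered scene (60 clutches, sd 50 nm, 20 um fov)."""
    return sim.make_clutch_scene(
        n_clusters=60, sites_per_cluster=20, cluster_sigma=50.0,
        fov=(20000.0, 20000.0), seed=11,
    )


@pytest.fixture(scope="session")
def clutch_kinetics():
    return sim.KineticsParams(
        site_on_rate=0.02, mean_residence=0.1, photon_rate=20000.0,
        duration=100.0, exposure=0.05,
    )


@pytest.fixture(scope="session")
def clutch_table(clutch_scene, clutch_kinetics):
    """Direct-mode localization table of the small clutch scene (20 nm precision)."""
    trace = sim.simulate_binding(clutch_scene, clutch_kinetics, seed=12)
    return sim.events_to_localizations(
        clutch_scene, trace, clutch_kinetics, precision_model=20.0, seed=13
    )


@pytest.fixture(scope="session")
def dense_table():
    """Dense static scene (~1e5 localizations) for FRC-regime checks."""
    scene = sim.make_clutch_scene(300, 20, 50.0, (10000.0, 10000.0), seed=21)
    kin = sim.KineticsParams(site_on_rate=0.05, mean_residence=0.1,
                             duration=200.0, exposure=0.05)
    trace = sim.simulate_binding(scene, kin, seed=22)
    return sim.events_to_localizations(scene, trace, kin, precision_model=20.0, seed=23)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
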