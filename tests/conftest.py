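import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from loopblock import synthetic as syn  # noqa: E402


@pytest.fixture(scope="session")
def optics():
    return syn.OpticsConfig()


@pytest.fixture(scope="session")
def nontopo_kin(optics):
    return syn.simulate_kinematics(syn.SimulationConfig(model="nontopological"), optics)


@pytest.fixture(scope="session")
def pseudo_kin(optics):
    return syn.simulate_kinematics(syn.SimulationConfig(model="pseudotopological"), optics)


@pytest.fixture(scope="session")
def nontopo_noiseless(nontopo_kin, optics):
    return syn.render_movie(nontopo_kin, optics, noise=False)


@pytest.fixture(scope="session")
def pseudo_noiseless(pseudo_kin, optics):
    return syn.render_movie(pseudo_kin, optics, noise=False)


def dna_polyline_px(kin, optics, extra_um=0.4):
    """Contour polyline anchor-1 -> stem -> past the loop tip, in pixels."""
    a1 = np.asarray(kin.geometry["anchor1_um"])
    stem = np.asarray(kin.geometry["stem_um"])
    cfg = kin.config
    tip_len = kin.geometry["um_per_kb"] * (cfg.encounter_loop_kb + cfg.post_encounter_kb) / 2.0
    tip = stem + np.array([0.0, tip_len + extra_um])
    return np.array([a1, stem, tip]) / optics.pixel_size_um
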