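import numpy as np
import pytest

import intervalrt as irt


@pytest.fixture(scope="session")
def default_config() -> irt.RunConfig:
    return irt.RunConfig()


@pytest.fixture(scope="session")
def workspace(default_config) -> irt.PlanWorkspace:
    """Shared stages A+B on the packaged default phantom (60x60 slice)."""
    return irt.PlanWorkspace(default_config)


@pytest.fixture(scope="session")
def comparison(default_config, workspace):
    """Four-model robustness-vs-price table on the packaged phantom."""
    return irt.compare_models(
        default_config,
        models=("nominal", "ptv", "minimax", "interval"),
        theta_sweep=(10.0,),
        workspace=workspace,
    )


SMALL_PHANTOM = irt.ProstatePhantomConfig(
    shape=(24, 24, 1),
    spacing=(5.0, 5.0, 5.0),
    body_semiaxes=(55.0, 50.0, 1.0e4),
    ctv_center=(0.0, -5.0, 0.0),
    ctv_semiaxes=(15.0, 13.0, 13.0),
    bladder_center=(0.0, 25.0, 0.0),
    bladder_semiaxes=(16.0, 12.0, 12.0),
    rectum_center=(0.0, -28.0, 0.0),
    rectum_semiaxes=(9.0, 7.0, 9.0),
)

SMALL_CONFIG = irt.RunConfig(
    phantom=SMALL_PHANTOM,
    beams=irt.BeamSetup(gantry_angles_deg=(0.0, 120.0, 240.0), bixel_width_mm=10.0),
    max_iter=150,
)


@pytest.fixture(scope="session")
def small_config() -> irt.RunConfig:
    return SMALL_CONFIG


@pytest.fixture(scope="session")
def small_workspace(small_config) -> irt.PlanWorkspace:
    """Cheap workspace (24x24 slice, 3 beams) for gradient / end-to-end tests."""
    return irt.PlanWorkspace(small_config)


@pytest.fixture(scope="session")
def default_phantom():
    return irt.add_derived_structures(irt.make_prostate_phantom())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
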