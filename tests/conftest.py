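import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from membrane_gate.syngen import (  # noqa: E402
    Geometry,
    NPDesign,
    SynthSpec,
    generate_membrane,
)


@pytest.fixture(scope="session")
def flat_spec() -> SynthSpec:
    return SynthSpec(
        geometry=Geometry.FLAT,
        lateral_extent=12.0,
        lipid_spacing=0.8,
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def flat_frame(flat_spec):
    return generate_membrane(flat_spec)


@pytest.fixture(scope="session")
def noisy_frame():
    spec = SynthSpec(lateral_extent=20.0, lipid_spacing=0.5, noise_sd=0.1, seed=11)
    return generate_membrane(spec)


@pytest.fixture(scope="session")
def reference_design() -> NPDesign:
    return NPDesign(
        core_diameter=2.0,
        charge_scheme="Const",
        ligand_chemistry="hydrophobic",
        ionized_count=99,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
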