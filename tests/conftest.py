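import numpy as np
import pytest

from artseg import synthgen


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_field_template():
    """96x96 template compatible with both network presets' divisors."""
    return synthgen.FieldSpec(height=96, width=96, seed=0)


@pytest.fixture(scope="session")
def artifact_field():
    """One deterministic field with a centred ellipse artifact."""
    spec = synthgen.FieldSpec(
        seed=42,
        artifact_specs=(synthgen.ArtifactSpec(
            "ellipse", {"a": 15.0, "b": 10.0}, texture_contrast=0.35,
            position=(48, 48)),))
    return synthgen.generate_field(spec)
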