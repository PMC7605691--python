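import pytest

from seedwater import SimConfig, build_inpaper_fixture, generate_experiment


@pytest.fixture(scope="session")
def fixture_ds():
    """The reconstructed published treatment-mean dataset."""
    return build_inpaper_fixture()


@pytest.fixture()
def sim_factory():
    """Factory for simulated experiments with overridable study conditions."""

    def make(**overrides):
        cfg = SimConfig(**{**SimConfig().__dict__, **overrides})
        ds, log = generate_experiment(cfg)
        return cfg, ds, log

    return make
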