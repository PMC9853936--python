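import pytest

from corepromoter.simulate import SimConfig, simulate, write_fixture_suite


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The hand-built 5-gene / 5-sample regression fixture."""
    d = tmp_path_factory.mktemp("fixture")
    return write_fixture_suite(d)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic study shared across tests."""
    cfg = SimConfig(
        seed=11,
        n_samples_a=30,
        n_samples_b=40,
        n_genes=25,
        n_true_somatic=12,
        n_true_germline=5,
        germline_fraction=0.3,
        n_polymorphic_background=6,
        n_private_background=6,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_sim_dir(small_sim, tmp_path_factory):
    d = tmp_path_factory.mktemp("simdata")
    return small_sim.write(d)
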