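import numpy as np
import pytest

from thermosip import ExperimentDesign, SyntheticTruth


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign(seed=123)


@pytest.fixture(scope="session")
def noise_free_truth():
    return SyntheticTruth().with_noise(power=0.0, co2=0.0, abundance=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260917)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small on-disk synthetic bundle shared by pipeline-level tests."""
    from thermosip import simulate_experiment

    out = tmp_path_factory.mktemp("bundle") / "exp"
    design = ExperimentDesign(seed=11)
    truth = SyntheticTruth(
        enriched_taxa={
            "CON": tuple(f"OTU{i:04d}" for i in range(1, 16)),
            "ORG": tuple(f"OTU{i:04d}" for i in range(16, 31)),
        }
    )
    simulate_experiment(design, truth, out_dir=out, n_taxa=150, depth=4000)
    return out
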