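import numpy as np
import pytest

from sersev import (CompositionVector, GroupSpec, Spectrum, SpectrumSet,
                    SyntheticDatasetSpec, WavenumberGrid, generate_basis)


@pytest.fixture
def toy_grid():
    """A short analysis grid (same range, 200 points) for fast tests."""
    return WavenumberGrid(564.0, 1681.0, 200)


@pytest.fixture
def toy_spec(toy_grid):
    rng = np.random.default_rng(7)
    groups = tuple(
        GroupSpec(
            name=f"G{k}",
            n_spectra=5,
            mean_composition=CompositionVector.from_array(rng.dirichlet(np.full(20, 3.0))),
            dirichlet_concentration=50.0,
        )
        for k in range(2)
    )
    return SyntheticDatasetSpec(seed=7, grid=toy_grid, groups=groups,
                                noise_sd=0.0, baseline_amplitude=0.0)


@pytest.fixture
def toy_basis(toy_spec):
    return generate_basis(toy_spec)


@pytest.fixture
def flat_spectrum(toy_grid):
    return Spectrum(toy_grid, np.full(toy_grid.n_points, 3.0))


def make_spectrum(grid, y, **meta):
    return Spectrum(grid, np.asarray(y, dtype=float), meta)


@pytest.fixture(scope="session")
def synthetic_bundle(tmp_path_factory):
    """A full pipeline input bundle shared by the slower end-to-end tests."""
    from sersev import write_synthetic_bundle

    root = tmp_path_factory.mktemp("bundle")
    cfg_path = write_synthetic_bundle(root, seed=11)
    return cfg_path


@pytest.fixture(scope="session")
def pipeline_report(synthetic_bundle):
    from sersev import PipelineConfig, run_pipeline

    cfg = PipelineConfig.from_yaml(synthetic_bundle)
    return run_pipeline(cfg)
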