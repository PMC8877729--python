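import numpy as np
import pytest

import somaquant as sq


@pytest.fixture(scope="session")
def small_grid():
    return sq.VoxelGrid(16, 32, 32)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Small noisy phantom shared across read-only tests."""
    spec = sq.named_specs(small=True)["noisy"]
    stack, truth = sq.generate_phantom(spec, seed=101)
    return spec, stack, truth


@pytest.fixture(scope="session")
def noisy_result(noisy_phantom):
    """Full pipeline run on the small noisy phantom."""
    spec, stack, truth = noisy_phantom
    config = sq.RunConfig(
        thresholds=sq.recommended_thresholds(spec),
        deconvolution=sq.DeconvolutionParams(enabled=False),
        screening=sq.ScreeningParams(fixed_volume_threshold_um3=231.77),
    )
    return sq.process_stack(stack, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
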