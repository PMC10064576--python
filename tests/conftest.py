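import numpy as np
import pytest

from rootphen import PipelineConfig, process_image
from rootphen.synthetic import SyntheticSpec, generate_tissue, recommended_config


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


def disc_mask(shape, centre, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= radius**2


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A compact three-ring mosaic used where a fast end-to-end run suffices."""
    return SyntheticSpec(seed=21, n_ring_bands=3, width=1600, height=400)


@pytest.fixture(scope="session")
def synth(small_spec):
    """Generated mosaic + ground truth + pipeline result, shared per session."""
    img, truth = generate_tissue(small_spec)
    config = recommended_config(small_spec, seed=21)
    result = process_image(img, config)
    return {"spec": small_spec, "img": img, "truth": truth, "cfg": config, "res": result}
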