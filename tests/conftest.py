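import warnings

import pytest

import fibrometry as fm


@pytest.fixture(scope="session")
def default_config():
    return fm.PipelineConfig()


@pytest.fixture(scope="session")
def tlf_image_truth():
    """One seeded dense-network micrograph with its ground truth."""
    spec = fm.preset_spec("tlf", seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        image, truth = fm.generate_network(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def clean_fiber_image():
    """A noiseless, shading-free, artifact-free single-fiber image."""
    spec = fm.NetworkSpec(
        image_size_px=(256, 256),
        um_per_px=1.0,
        n_seeds=1,
        branch_prob=0.0,
        curvature_sd=0.0,
        fiber_width_um=5.0,
        width_jitter=0.0,
        length_jitter=0.0,
        fiber_length_um=100.0,
        noise_sd=0.0,
        shading_amplitude=0.0,
        n_blob_artifacts=0,
        seed=0,
    )
    image, truth = fm.generate_network(spec)
    return spec, image, truth
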