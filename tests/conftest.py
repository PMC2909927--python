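import numpy as np
import pytest

from irispipe.synthetic import EyeSpec, generate_iris_texture, render_eye
from irispipe.types import IrisCode


@pytest.fixture(scope="session")
def texture():
    return generate_iris_texture(7, 20, 240)


def make_eye(texture, pupil_radius=30.0, noise_sd=0.02, eyelid_coverage=0.0,
             size=160, limbal_radius=60.0, pupil_offset=(2.0, -1.0),
             noise_seed=0, spots=(), mean_intensity=(0.1, 0.5, 0.9)):
    c = size / 2
    spec = EyeSpec(height=size, width=size,
                   pupil_center=(c + pupil_offset[0], c + pupil_offset[1]),
                   pupil_radius=pupil_radius,
                   limbal_center=(c, c), limbal_radius=limbal_radius,
                   texture_seed=texture.seed, mean_intensity=mean_intensity,
                   noise_sd=noise_sd, eyelid_coverage=eyelid_coverage,
                   specular_spots=spots, noise_seed=noise_seed)
    img, truth = render_eye(spec, texture)
    return spec, img, truth


@pytest.fixture(scope="session")
def clean_eye(texture):
    """Noiseless, occlusion-free eye with mild pupil/limbus non-concentricity."""
    return make_eye(texture, noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_eye(texture):
    return make_eye(texture)


def random_code(rng, shape=(20, 240, 2), mask_p=0.0):
    bits = rng.random(shape) < 0.5
    mask = rng.random(shape) >= mask_p if mask_p else np.ones(shape, dtype=bool)
    return IrisCode(bits, mask)
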