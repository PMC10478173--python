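import numpy as np
import pytest

from myoscreen.synthetic import MovieSpec, StackSpec, _speckle_texture


def speckle(seed: int = 0, size: int = 128) -> np.ndarray:
    """Speckle texture frame for correlation tests."""
    spec = MovieSpec(height_px=size, width_px=size, seed=seed)
    return _speckle_texture(spec, np.random.default_rng(seed))


def stripe_image(theta_deg: float, n: int = 192, period: float = 12.0) -> np.ndarray:
    """Sinusoidal stripes whose structures run along ``theta_deg``."""
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    t = np.deg2rad(theta_deg)
    return np.cos((-xx * np.sin(t) + yy * np.cos(t)) * 2.0 * np.pi / period)


@pytest.fixture
def small_movie_spec() -> MovieSpec:
    """Fast movie used by pipeline-level tests."""
    return MovieSpec(
        height_px=64, width_px=64, n_frames=12, amplitude_um=3.0,
        contraction_axis_deg=90.0, axis_anisotropy=0.8,
        pulse_times_s=(0.1,), pulse_width_s=0.4, noise_sigma=0.005, seed=42,
    )


@pytest.fixture
def small_stack_spec() -> StackSpec:
    """Fast 4-channel stack used by quantification tests."""
    return StackSpec(
        shape_zyx=(5, 128, 128), n_fibers=4, fiber_length_um=40.0,
        n_axons=2, axon_total_length_um=300.0,
        n_pre_puncta=12, n_post_puncta=12, colocalization_fraction=0.5,
        seed=7,
    )
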