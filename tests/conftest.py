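import numpy as np
import pytest

from pulsevit import SyntheticScene, gen_dataset, gen_ppg_trace, render_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_scene(hr=72.0, duration=10.0, fps=25.0, depth=0.05, noise=0.0,
               motion=0.0, size=(64, 64), seed=3):
    """Small constant-HR scene used across tests."""
    ppg = gen_ppg_trace(lambda t: hr, duration, 60.0, seed=seed)
    return SyntheticScene(ppg=ppg, frame_rate=fps, image_size=size,
                          modulation_depth=depth, noise_sd=noise,
                          motion_amplitude=motion, seed=seed)


@pytest.fixture(scope="session")
def small_scene_render():
    """One rendered 10 s scene at 72 BPM, shared across tests."""
    scene = make_scene()
    frames, landmarks, hr_rows = render_scene(scene)
    return scene, frames, landmarks, hr_rows


@pytest.fixture(scope="session")
def micro_manifest(tmp_path_factory):
    """Two short synthetic videos for cheap pipeline tests."""
    out = tmp_path_factory.mktemp("micro")
    return gen_dataset(2, (60, 100), duration=6.0, fps=25.0, seed=11, out_dir=out)


@pytest.fixture(scope="session")
def fixture_manifest(tmp_path_factory):
    """The 8-video constant-HR training fixture (50-110 BPM, 30 s, 25 FPS)."""
    out = tmp_path_factory.mktemp("fix8")
    return gen_dataset(8, (50, 110), duration=30.0, fps=25.0, seed=7, out_dir=out)
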