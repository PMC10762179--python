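import numpy as np
import pytest

from epimux import scenes
from epimux.image_io import AnalysisConfig


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def reference_scene():
    """Mixed noisy scene plus its render and ground truth."""
    spec = scenes.random_scene(seed=11, shape=(384, 384))
    image, gt = scenes.render_scene(spec)
    return spec, image, gt


@pytest.fixture
def noisefree_scene():
    spec = scenes.random_scene(seed=11, shape=(384, 384), noise_sigma=0.0)
    image, gt = scenes.render_scene(spec)
    return spec, image, gt


def random_mask_triple(rng: np.random.Generator, shape=(64, 64), p=0.2):
    return {name: rng.random(shape) < p for name in ("A", "B", "C")}


def coverage_counts(masks: dict) -> np.ndarray:
    """Independent per-pixel enumeration oracle: coverage count per pixel."""
    stack = np.stack([np.asarray(m, dtype=bool) for m in masks.values()])
    return stack.sum(axis=0)
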