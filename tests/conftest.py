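import numpy as np
import pytest
from hypothesis import settings

from fogkit.pipeline import PipelineConfig, run_detection

settings.register_profile("fogkit", derandomize=True, deadline=None)
settings.load_profile("fogkit")
from fogkit.synthetic import generate, preset_scenarios


@pytest.fixture(scope="session")
def presets():
    """Generated (recording, ground truth) for every named scenario."""
    return {name: generate(cfg) for name, cfg in preset_scenarios().items()}


@pytest.fixture(scope="session")
def detection_results(presets):
    """Full pipeline output per preset, FI on the Fig.-style 4 s profile."""
    cfg = PipelineConfig()
    cfg.fi.window_s = 4.0
    cfg.fi.threshold = 0.1
    return {name: run_detection(rec, cfg) for name, (rec, _) in presets.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
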