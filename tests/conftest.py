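import numpy as np
import pytest

from jujubenet.models import CBAMConfig, MDCVariant, ModelConfig, StageConfig
from jujubenet.synthetic_data import build_dataset

# Small stage configuration used for CPU-scale training runs.
REDUCED_STAGES = StageConfig(depths=(1, 1, 2, 1), dims=(24, 48, 96, 192))
REDUCED_IMAGE_SIZE = 64


def reduced_model_config(num_classes: int = 6) -> ModelConfig:
    return ModelConfig(
        num_classes=num_classes,
        stage_config=REDUCED_STAGES,
        mdc_variant=MDCVariant(),
        cbam=CBAMConfig(reduction_ratio=8),
    )


@pytest.fixture(scope="session")
def corpus60(tmp_path_factory):
    """Materialized 60-base-per-class synthetic corpus at 64x64 (1800 images)."""
    out = tmp_path_factory.mktemp("corpus60")
    return build_dataset(60, out, seed=20, image_size=REDUCED_IMAGE_SIZE)


@pytest.fixture(scope="session")
def corpus10(tmp_path_factory):
    """Small materialized corpus (10 bases per class, 300 images)."""
    out = tmp_path_factory.mktemp("corpus10")
    return build_dataset(10, out, seed=7, image_size=32)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
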