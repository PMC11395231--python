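import numpy as np
import pytest

from hybridscope.latent import (
    BetaSchedule,
    VAEConfig,
    encode,
    feature_table,
    normalize_crops,
    train_vae,
)
from hybridscope.simgen import FieldConfig, generate_crop_set, generate_field


@pytest.fixture(scope="session")
def small_field():
    """A modest field with planted hybrid and tumor cells plus ground truth."""
    config = FieldConfig(
        height_px=448,
        width_px=448,
        n_leukocytes=30,
        n_chc=3,
        n_ctc=1,
        n_control_cells=100,
        seed=42,
    )
    return generate_field(config)


@pytest.fixture(scope="session")
def two_class_training():
    """One shared training run on the two-phenotype crop fixture.

    Session-scoped because full-architecture training dominates suite
    runtime; tests that only need a trained encoder reuse it.
    """
    crops = normalize_crops(generate_crop_set(200, 200, 0.0, seed=1))
    model, history = train_vae(crops, VAEConfig(seed=5, max_epochs=30), BetaSchedule())
    embeddings = encode(model, crops, feature_table=feature_table(crops))
    return {"crops": crops, "model": model, "history": history, "embeddings": embeddings}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
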