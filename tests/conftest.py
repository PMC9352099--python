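import numpy as np
import pytest

from dermopipe import scnn, synth


@pytest.fixture(scope="session")
def lesion_fixtures():
    """50 synthetic lesions (25 per class) at full frame size with truth masks."""
    samples, index = synth.generate_dataset(25, seed=5, image_side=224)
    return samples, index


@pytest.fixture(scope="session")
def reduced_training_run():
    """One seeded reduced-profile training run: 200 samples/class at 64x64,
    20 epochs of Adam 0.001.  Shared by the learning and robustness checks."""
    samples, index = synth.generate_dataset(200, seed=11, image_side=64)
    x = np.stack([s.image for s in samples])
    y = (index["label"] == "malignant").astype(int).to_numpy()
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(x))
    x, y = x[perm], y[perm]
    n_train = 320
    cfg = scnn.TrainConfig(optimizer="adam", learning_rate=0.001, batch_size=32, epochs=20, seed=0)
    model = scnn.build_model(scnn.ModelSpec.reduced(), seed=0)
    model = scnn.train(model, x[:n_train], y[:n_train], x[n_train:], y[n_train:], cfg)
    return {
        "model": model,
        "x_val": x[n_train:],
        "y_val": y[n_train:],
        "cfg": cfg,
    }
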