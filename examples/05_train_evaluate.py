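"""Train the reduced-profile shallow CNN on synthetic data and evaluate it.

A desk-scale run: 60 samples per class at 64x64, reduced filter counts,
8 epochs of Adam 0.001.  The full 224x224 profile has the same layer stack
with filters 16/32/32/64 and a 1024-unit dense head.
"""

import numpy as np

from dermopipe import scnn, synth
from dermopipe.evalmetrics import confusion, metrics, roc_auc

samples, index = synth.generate_dataset(60, seed=1, image_side=64)
x = np.stack([s.image for s in samples])
y = (index["label"] == "malignant").astype(int).to_numpy()
perm = np.random.default_rng(0).permutation(len(x))
x, y = x[perm], y[perm]
n_train, n_val = 80, 20

for layer, side, ch in scnn.forward_shapes(scnn.ModelSpec.reduced()):
    print(f"  {layer:8s} {side:4d} x {side:<4d} x {ch}")

cfg = scnn.TrainConfig(optimizer="adam", learning_rate=0.001, batch_size=16, epochs=8, seed=0)
model = scnn.build_model(scnn.ModelSpec.reduced(), seed=0)
model = scnn.train(model, x[:n_train], y[:n_train],
                   x[n_train : n_train + n_val], y[n_train : n_train + n_val], cfg)
print(f"best epoch (min val loss): {model.best_epoch + 1}")

x_test, y_test = x[n_train + n_val :], y[n_train + n_val :]
probs, pred = scnn.predict(model, x_test)
rep = metrics(confusion(y_test, pred))
_, auc = roc_auc(y_test, probs[:, 1])
print(f"test accuracy {rep.accuracy:.1f}%  recall {rep.recall:.1f}%"
      f"  precision {rep.precision:.1f}%  F1 {rep.f1:.1f}%  AUC {100 * auc:.1f}%")
# The synthetic classes differ mainly in lesion darkness and border
# irregularity, so even this small network separates them within a few epochs.
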