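"""The gradient-boosting classifier on a toy problem, stage by stage.

Boosting starts from the loss-minimizing constant (the log-odds of the
positive rate), then repeatedly fits a regression tree to the negative
gradient of the binomial deviance and takes a line-searched step.
"""

import numpy as np

from spbcmi import gbdt

rng = np.random.default_rng(0)
X = rng.normal(size=(300, 2))
y = ((X[:, 0] ** 2 + X[:, 1] ** 2) < 1.2).astype(float)  # a disc: not linearly separable

model = gbdt.fit(X, y, n_stages=100, learning_rate=0.1, max_depth=3)

print(f"initial constant F0 = {model.F0:.4f} "
      f"(log-odds of positive rate {y.mean():.3f})")
losses = model.train_loss_
print(f"training deviance: {losses[0]:.2f} -> {losses[-1]:.2f} over "
      f"{len(model.stages)} stages (monotone non-increasing)")
acc = np.mean((gbdt.predict_proba(model, X) >= 0.5) == y)
print(f"training accuracy: {acc:.3f}")
# Depth-3 trees carve the disc boundary out of axis-aligned splits; the
# line-searched step size gamma_m rescales each tree's residual fit.
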