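"""REW-NPLS: online updates, factor selection, and forgetting.

Streams mini-batches into a recursive decoder, printing the selected
factor count and held-out error as it learns; then shows how a
forgetting factor below one helps after an abrupt regime change.
"""

import numpy as np

from aabci.rew import rew_init, rew_predict, rew_update

SHAPE = (4, 3, 5)
rng = np.random.default_rng(0)
W = rng.standard_normal((np.prod(SHAPE), 2))


def batch(n, flip=1.0):
    X = rng.standard_normal((n,) + SHAPE)
    Y = flip * X.reshape(n, -1) @ W * 0.2 + 0.3 * rng.standard_normal((n, 2))
    return X, Y


Xt, Yt = batch(500)
state = rew_init(SHAPE, 2, lam=1.0, f_max=8)
print("update | f* | held-out MSE")
for u in range(8):
    rew_update(state, *batch(100))
    mse = np.mean((rew_predict(state, Xt) - Yt) ** 2)
    print(f"{u + 1:6d} | {state.f_star:2d} | {mse:.4f}")

print("\nabrupt regime flip (labels negated), then three more updates:")
for lam in (1.0, 0.5):
    s = rew_init(SHAPE, 2, lam=lam, f_max=8)
    for _ in range(5):
        rew_update(s, *batch(100))
    for _ in range(3):
        rew_update(s, *batch(100, flip=-1.0))
    mse = np.mean((rew_predict(s, Xt) + Yt) ** 2)  # new-regime target
    print(f"  lam={lam}: new-regime MSE {mse:.4f}")
print("Forgetting (lam < 1) discounts the stale regime and adapts faster.")
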