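"""Multi-branch feed-forward regressor, implemented in numpy.

The network mirrors the heterogeneous structure of the feature sets:
the scalar-descriptor block and the PSD-summary block each pass through
their own stack of hidden layers; the resulting representations are
concatenated with the raw materials+processes block and fed through
joint hidden layers to a single linear output.

Training is mini-batch Adam on mean squared error with inverted
dropout, early stopping on Dev RMSE (patience 20, best weights
restored) and learning-rate halving after a 10-epoch plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ACTIVATIONS = ("relu", "tanh", "elu", "swish")


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh(z)
    if name == "elu":
        return np.where(z > 0, z, np.expm1(z))
    if name == "swish":
        return z / (1.0 + np.exp(-z))
    raise ValueError(name)


def _act_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(z.dtype)
    if name == "tanh":
        return 1.0 - a**2
    if name == "elu":
        return np.where(z > 0, 1.0, a + 1.0)
    if name == "swish":
        sig = 1.0 / (1.0 + np.exp(-z))
        return sig * (1.0 + z * (1.0 - sig))
    raise ValueError(name)


@dataclass
class NNConfig:
    """Hyperparameters of the multi-branch net (search space in
    :data:`tabletpred.model_zoo.NN_SEARCH_SPACE`)."""

    learning_rate: float = 1e-3
    activation: str = "relu"
    dropout: float = 0.1
    descriptor_layers: tuple[int, ...] = (64,)
    psd_layers: tuple[int, ...] = (32,)
    joint_layers: tuple[int, ...] = (64,)
    batch_size: int = 32
    epochs: int = 100

    patience: int = 20  # early-stopping patience on Dev RMSE
    lr_plateau: int = 10  # halve LR after this many epochs w/o improvement


class _Stack:
    """A stack of dense layers with a shared activation."""

    def __init__(self, sizes: list[int], activation: str, rng: np.random.Generator):
        self.activation = activation
        self.W, self.b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    def forward(self, x, rng=None, dropout=0.0, cache=None):
        a = x
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            h = _act(self.activation, z)
            mask = None
            if rng is not None and dropout > 0.0:
                mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
                h = h * mask
            if cache is not None:
                cache.append((a, z, h, mask))
            a = h
        return a

    def backward(self, grad, cache, grads_W, grads_b):
        for i in range(len(self.W) - 1, -1, -1):
            a_in, z, h, mask = cache[i]
            if mask is not None:
                grad = grad * mask
            act_val = h if mask is None else _act(self.activation, z)
            grad = grad * _act_grad(self.activation, z, act_val)
            grads_W[i][...] = a_in.T @ grad
            grads_b[i][...] = grad.sum(axis=0)
            grad = grad @ self.W[i].T
        return grad

    @property
    def params(self):
        return self.W + self.b


class MultiBranchRegressor:
    """Three-input-branch MLP regressor (see module docstring).

    ``fit`` takes the feature blocks as a dict with keys ``main``,
    ``descriptor`` and ``psd`` (arrays with zero-width allowed; an empty
    block skips its branch).
    """

    def __init__(self, config: NNConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        self._built = False

    def _build(self, widths: dict[str, int]) -> None:
        rng = np.random.default_rng(self.seed)
        cfg = self.config
        self.branches = {}
        concat = widths["main"]
        for key, layers in (("descriptor", cfg.descriptor_layers), ("psd", cfg.psd_layers)):
            if widths[key] > 0:
                self.branches[key] = _Stack([widths[key], *layers], cfg.activation, rng)
                concat += layers[-1]
            else:
                self.branches[key] = None
        self.joint = _Stack([concat, *cfg.joint_layers], cfg.activation, rng)
        limit = np.sqrt(6.0 / (cfg.joint_layers[-1] + 1))
        self.W_out = rng.uniform(-limit, limit, size=(cfg.joint_layers[-1], 1))
        self.b_out = np.zeros(1)
        self._built = True

    def _forward(self, blocks, rng=None, caches=None):
        cfg = self.config
        parts = [blocks["main"]]
        for key in ("descriptor", "psd"):
            stack = self.branches[key]
            if stack is not None:
                cache = [] if caches is not None else None
                parts.append(
                    stack.forward(blocks[key], rng=rng, dropout=cfg.dropout, cache=cache)
                )
                if caches is not None:
                    caches[key] = cache
            elif caches is not None:
                caches[key] = None
        concat = np.concatenate(parts, axis=1)
        cache = [] if caches is not None else None
        h = self.joint.forward(concat, rng=rng, dropout=cfg.dropout, cache=cache)
        if caches is not None:
            caches["joint"] = cache
            caches["concat"] = concat
            caches["widths"] = [p.shape[1] for p in parts]
        return (h @ self.W_out + self.b_out).ravel()

    def predict(self, blocks: dict[str, np.ndarray]) -> np.ndarray:
        if not self._built:
            raise RuntimeError("model is not fitted")
        blocks = {k: np.asarray(v, dtype=float) for k, v in blocks.items()}
        return self._forward(blocks)

    def fit(self, blocks, y, dev_blocks=None, dev_y=None) -> "MultiBranchRegressor":
        cfg = self.config
        blocks = {k: np.asarray(v, dtype=float) for k, v in blocks.items()}
        y = np.asarray(y, dtype=float).ravel()
        self._build({k: blocks[k].shape[1] for k in ("main", "descriptor", "psd")})
        rng = np.random.default_rng(self.seed + 1)

        params = []
        for key in ("descriptor", "psd"):
            if self.branches[key] is not None:
                params += self.branches[key].params
        params += self.joint.params
        params += [self.W_out, self.b_out]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        lr = cfg.learning_rate
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        n = len(y)
        best_rmse, best_state, wait = np.inf, None, 0
        self.history_ = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                batch = {k: blocks[k][idx] for k in blocks}
                caches = {}
                pred = self._forward(batch, rng=rng, caches=caches)
                err = (pred - y[idx])[:, None] * (2.0 / len(idx))

                grads = [np.zeros_like(p) for p in params]
                # map parameter gradients back through the stacks
                h_last = caches["joint"][-1][2]
                gW_out = h_last.T @ err
                gb_out = err.sum(axis=0)
                grad = err @ self.W_out.T

                offset = len(params) - 2
                grads[offset][...] = gW_out
                grads[offset + 1][...] = gb_out

                joint_stack = self.joint
                nj = len(joint_stack.W)
                joint_off = offset - 2 * nj
                gW = [grads[joint_off + i] for i in range(nj)]
                gb = [grads[joint_off + nj + i] for i in range(nj)]
                grad = joint_stack.backward(grad, caches["joint"], gW, gb)

                # split the concat gradient back into branch outputs
                widths = caches["widths"]
                splits = np.cumsum(widths)[:-1]
                pieces = np.split(grad, splits, axis=1)
                pi = 1
                branch_off = 0
                for key in ("descriptor", "psd"):
                    stack = self.branches[key]
                    if stack is None:
                        continue
                    nb = len(stack.W)
                    gW = [grads[branch_off + i] for i in range(nb)]
                    gb = [grads[branch_off + nb + i] for i in range(nb)]
                    stack.backward(pieces[pi], caches[key], gW, gb)
                    branch_off += 2 * nb
                    pi += 1

                t += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    if not np.all(np.isfinite(g)):
                        raise FloatingPointError("non-finite gradient")
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g**2
                    mhat = mi / (1 - beta1**t)
                    vhat = vi / (1 - beta2**t)
                    p -= lr * mhat / (np.sqrt(vhat) + eps)

            if dev_blocks is not None:
                dev_pred = self.predict(dev_blocks)
                rmse = float(np.sqrt(np.mean((dev_pred - np.asarray(dev_y).ravel()) ** 2)))
            else:
                pred = self.predict(blocks)
                rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
            self.history_.append(rmse)
            if not np.isfinite(rmse):
                raise FloatingPointError("non-finite validation loss")
            if rmse < best_rmse - 1e-12:
                best_rmse, wait = rmse, 0
                best_state = [p.copy() for p in params]
            else:
                wait += 1
                if wait % cfg.lr_plateau == 0:
                    lr *= 0.5
                if wait >= cfg.patience:
                    break
        if best_state is not None:
            for p, s in zip(params, best_state):
                p[...] = s
        self.best_dev_rmse_ = best_rmse
        return self
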