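"""Parameterized layers over the tensor tape."""

from __future__ import annotations

import numpy as np

from vemseg.nn.tensor import Tensor, batchnorm2d, conv2d

__all__ = ["Module", "Conv2d", "BatchNorm2d"]


class Module:
    """Base class: recursive parameter/state collection and train/eval mode."""

    def modules(self):
        for v in vars(self).values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        yield m
                        yield from m.modules()

    def parameters(self):
        params = []
        for m in [self, *self.modules()]:
            params.extend(getattr(m, "_params", []))
        return params

    def named_state(self):
        """Flat name -> array mapping of parameters and batch-norm statistics."""
        state = {}
        for i, m in enumerate([self, *self.modules()]):
            for j, p in enumerate(getattr(m, "_params", [])):
                state[f"m{i}.p{j}"] = p.data
            for key, arr in getattr(m, "_buffers", {}).items():
                state[f"m{i}.{key}"] = arr
        return state

    def load_state(self, state):
        for i, m in enumerate([self, *self.modules()]):
            for j, p in enumerate(getattr(m, "_params", [])):
                p.data = np.asarray(state[f"m{i}.p{j}"], dtype=np.float32).reshape(p.data.shape)
            bufs = getattr(m, "_buffers", {})
            for key in bufs:
                bufs[key] = np.asarray(state[f"m{i}.{key}"], dtype=np.float32)
            if bufs and hasattr(m, "running"):
                m.running = {"mean": bufs["running_mean"], "var": bufs["running_var"]}

    def set_training(self, flag: bool):
        for m in [self, *self.modules()]:
            m.training = flag


class Conv2d(Module):
    """Convolution with He fan-in init drawn from the supplied RNG."""

    def __init__(self, cin, cout, k, stride=1, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.w = Tensor(w.astype(np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None
        self.stride = stride
        self._params = [self.w] + ([self.b] if bias else [])

    def __call__(self, x):
        return conv2d(x, self.w, self.b, stride=self.stride)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self._buffers = {
            "running_mean": np.zeros(c, dtype=np.float32),
            "running_var": np.ones(c, dtype=np.float32),
        }
        self.running = {"mean": self._buffers["running_mean"], "var": self._buffers["running_var"]}
        self.momentum = momentum
        self.eps = eps
        self.training = True
        self._params = [self.gamma, self.beta]

    def __call__(self, x):
        out = batchnorm2d(x, self.gamma, self.beta, self.running,
                          training=self.training, momentum=self.momentum, eps=self.eps)
        # keep buffer dict in sync (batchnorm2d rebinds dict values)
        self._buffers["running_mean"] = self.running["mean"]
        self._buffers["running_var"] = self.running["var"]
        return out
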