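"""Neural-network building blocks on top of :mod:`scdiff.autodiff`.

Layers follow the usual Module/Parameter pattern: parameters are leaf
tensors with ``requires_grad=True``; ``state_dict`` / ``load_state_dict``
move raw numpy arrays in and out for checkpointing.  All random
initialization draws from an explicitly passed ``numpy.random.Generator``
so model construction is deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigurationError

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.ascontiguousarray(data), requires_grad=True)


class Module:
    def __init__(self):
        self._modules: dict[str, "Module"] = {}
        self._params: dict[str, Parameter] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix=""):
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ConfigurationError(f"state dict key mismatch: {sorted(missing)[:5]}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ConfigurationError(f"shape mismatch for {k}")
            p.data = np.ascontiguousarray(arr)

    def num_parameters(self):
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng, stride=1, padding=None, groups=1,
                 bias=True, zero_init=False, dtype=DTYPE):
        super().__init__()
        if cin % groups or cout % groups:
            raise ConfigurationError("channels not divisible by groups")
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        fan_in = (cin // groups) * k * k
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            (rng.standard_normal((cout, cin // groups, k, k)) * scale).astype(dtype)
        )
        self.bias = Parameter(np.zeros(cout, dtype=dtype)) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, groups=self.groups)


class Linear(Module):
    def __init__(self, nin, nout, rng, zero_init=False, dtype=DTYPE):
        super().__init__()
        scale = 0.0 if zero_init else np.sqrt(1.0 / nin)
        self.weight = Parameter((rng.standard_normal((nin, nout)) * scale).astype(dtype))
        self.bias = Parameter(np.zeros(nout, dtype=dtype))

    def forward(self, x):
        return ad.add(ad.matmul(x, self.weight), self.bias)


class GroupNorm(Module):
    """Group normalization with per-channel affine (gamma, shift z)."""

    def __init__(self, num_groups, channels, eps=1e-5, dtype=DTYPE):
        super().__init__()
        if channels % num_groups:
            raise ConfigurationError("num_groups must divide channel count")
        self.num_groups = num_groups
        self.channels = channels
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.shift = Parameter(np.zeros(channels, dtype=dtype))

    def normalize(self, x):
        """Zero-mean unit-variance per (batch, group), before affine."""
        B, C, H, W = x.shape
        G = self.num_groups
        xg = ad.reshape(x, (B, G, C // G * H * W))
        mu = ad.tmean(xg, axis=2, keepdims=True)
        xc = ad.sub(xg, mu)
        var = ad.tmean(ad.mul(xc, xc), axis=2, keepdims=True)
        xn = ad.div(xc, ad.sqrt(ad.add(var, self.eps)))
        return ad.reshape(xn, (B, C, H, W))

    def forward(self, x):
        xn = self.normalize(x)
        g = ad.reshape(self.gamma, (1, self.channels, 1, 1))
        z = ad.reshape(self.shift, (1, self.channels, 1, 1))
        return ad.add(ad.mul(xn, g), z)


class Dropout(Module):
    """Inverted dropout; owns a private RNG stream for reproducibility."""

    def __init__(self, p, rng):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ConfigurationError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(rng.integers(2**31))

    def forward(self, x):
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return ad.mul(x, Tensor(mask))


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = ModuleList(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


def sinusoidal_embedding(t, dim, max_period=10000.0, dtype=DTYPE):
    """Standard transformer-style embedding of integer timesteps.

    t: scalar or (B,) array of timesteps -> (B, dim) numpy array.
    """
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / half)
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.cos(args), np.sin(args)], axis=1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((emb.shape[0], 1))], axis=1)
    return emb.astype(dtype)


def global_norm(params):
    sq = 0.0
    for p in params:
        if p.grad is not None:
            sq += float(np.sum(p.grad.astype(np.float64) ** 2))
    return np.sqrt(sq)


class Adam:
    """Adam optimizer with optional global gradient-norm clipping."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8, clip_norm=None):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        scale = 1.0
        if self.clip_norm is not None:
            norm = global_norm(self.params)
            if norm > self.clip_norm and norm > 0:
                scale = self.clip_norm / norm
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self):
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state):
        self.t = int(state["t"])
        self.m = [np.asarray(m).copy() for m in state["m"]]
        self.v = [np.asarray(v).copy() for v in state["v"]]
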