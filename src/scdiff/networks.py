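"""The six networks of the artifact-correction model.

Match module: two translation generators (pCT -> fake CBCT and back) with a
discriminator each.  Diffusive module: a conditional UNet generator
``G_alpha(x_t, condition, t)`` predicting the clean image from a noisy
sample, a condition image and a timestep, plus a conditional PatchGAN
discriminator scoring reverse transitions.

Both generator families end in a global residual applied in inverse-tanh
space: the network's final (zero-initialized) convolution adds a correction
to ``atanh(clip(base))`` before the output ``tanh``, so a freshly built
matcher is the identity map and a freshly built diffusive generator passes
its condition through.  Outputs therefore always lie in [-1, 1] and
training starts from a sensible operating point instead of noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .errors import ConfigurationError
from .scconv import CRUParams, SCConv, SRUParams
from .schedule import NoiseSchedule

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "LossWeights",
    "ScDiffModel",
    "build_matcher_generator",
    "build_diffusive_generator",
    "build_discriminator",
    "build_model",
]

ATANH_CLIP = 0.999


@dataclass(frozen=True)
class GeneratorSpec:
    base_channels: int = 32
    depth: int = 3
    use_scconv: bool = False
    dropout: float = 0.0
    time_embed_dim: int = 64
    n_res_blocks: int = 2

    def __post_init__(self):
        if self.depth < 2:
            raise ConfigurationError("depth must be >= 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class DiscriminatorSpec:
    base_channels: int = 32
    n_layers: int = 3
    conditional: bool = False
    time_embed_dim: int = 64

    def __post_init__(self):
        if self.n_layers < 2:
            raise ConfigurationError("n_layers must be >= 2")


@dataclass(frozen=True)
class LossWeights:
    lambda1: float = 10.0   # match cycle
    lambda2: float = 10.0   # diffusive cycle
    lambda3: float = 0.5    # match adversarial
    lambda4: float = 0.5    # diffusive adversarial
    eta: float = 1.0        # gradient penalty

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda3, self.lambda4, self.eta) < 0:
            raise ConfigurationError("loss weights must be nonnegative")


def _check_divisible(h, w, depth):
    if h % (1 << depth) or w % (1 << depth):
        raise ConfigurationError(
            f"input {h}x{w} not divisible by 2^{depth}; pick a compatible size"
        )


def _gn_groups(c):
    for g in (8, 4, 2, 1):
        if c % g == 0:
            return g
    return 1


def _atanh(x):
    # atanh(x) = 0.5 * log((1+x)/(1-x)), x already clipped away from +-1
    return ad.mul(0.5, ad.log(ad.div(ad.add(1.0, x), ad.sub(1.0, x))))


class ResBlock(nn.Module):
    """GN -> SiLU -> conv3x3 (+ time affine) -> GN -> SiLU -> dropout -> conv3x3."""

    def __init__(self, cin, cout, rng, time_dim=None, dropout=0.0):
        super().__init__()
        self.norm1 = nn.GroupNorm(_gn_groups(cin), cin)
        self.conv1 = nn.Conv2d(cin, cout, 3, rng)
        self.norm2 = nn.GroupNorm(_gn_groups(cout), cout)
        self.drop = nn.Dropout(dropout, rng)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng, zero_init=True)
        self.time_proj = nn.Linear(time_dim, 2 * cout, rng, zero_init=True) if time_dim else None
        self.skip = nn.Conv2d(cin, cout, 1, rng, bias=False) if cin != cout else None

    def forward(self, x, temb=None):
        h = self.conv1(ad.silu(self.norm1(x)))
        if self.time_proj is not None and temb is not None:
            ts = self.time_proj(temb)  # (B, 2*cout)
            cout = h.shape[1]
            scale = ad.reshape(ts[:, :cout], (h.shape[0], cout, 1, 1))
            shift = ad.reshape(ts[:, cout:], (h.shape[0], cout, 1, 1))
            h = ad.add(ad.mul(h, ad.add(1.0, scale)), shift)
        h = self.conv2(self.drop(ad.silu(self.norm2(h))))
        base = x if self.skip is None else self.skip(x)
        return ad.add(base, h)


class MatcherGenerator(nn.Module):
    """Residual encoder-decoder for unpaired slice translation."""

    def __init__(self, spec: GeneratorSpec, rng):
        super().__init__()
        self.spec = spec
        c = spec.base_channels
        self.stem = nn.Conv2d(1, c, 3, rng)
        downs, chans = [], c
        for _ in range(spec.depth - 1):
            downs.append(nn.Conv2d(chans, 2 * chans, 3, rng, stride=2))
            chans *= 2
        self.downs = nn.ModuleList(downs)
        self.blocks = nn.ModuleList(
            [ResBlock(chans, chans, rng, dropout=spec.dropout)
             for _ in range(spec.n_res_blocks)]
        )
        ups = []
        for _ in range(spec.depth - 1):
            ups.append(nn.Conv2d(chans, chans // 2, 3, rng))
            chans //= 2
        self.ups = nn.ModuleList(ups)
        self.out_norm = nn.GroupNorm(_gn_groups(chans), chans)
        self.out_conv = nn.Conv2d(chans, 1, 3, rng, zero_init=True)

    def forward(self, x):
        _check_divisible(x.shape[2], x.shape[3], self.spec.depth - 1)
        h = self.stem(x)
        for d in self.downs:
            h = ad.leaky_relu(d(h), 0.2)
        for b in self.blocks:
            h = b(h)
        for u in self.ups:
            h = ad.leaky_relu(u(ad.upsample_nearest2x(h)), 0.2)
        delta = self.out_conv(ad.silu(self.out_norm(h)))
        base = _atanh(ad.clip(x, -ATANH_CLIP, ATANH_CLIP))
        return ad.tanh(ad.add(delta, base))


class DiffusiveGenerator(nn.Module):
    """Conditional UNet predicting the clean image from (x_t, condition, t).

    The noisy sample and the condition are concatenated on the channel axis;
    the timestep enters through a sinusoidal embedding -> MLP -> per-level
    affine modulation inside every residual block.  SCConv blocks sit in the
    downsampling path when ``spec.use_scconv`` is set.
    """

    def __init__(self, spec: GeneratorSpec, rng):
        super().__init__()
        self.spec = spec
        c = spec.base_channels
        td = spec.time_embed_dim
        self.time_mlp1 = nn.Linear(td, td, rng)
        self.time_mlp2 = nn.Linear(td, td, rng)
        self.stem = nn.Conv2d(2, c, 3, rng)
        enc_blocks, enc_scconv, downs = [], [], []
        chans = c
        self.enc_channels = [c]
        for _ in range(spec.depth):
            enc_blocks.append(ResBlock(chans, chans, rng, time_dim=td, dropout=spec.dropout))
            enc_scconv.append(SCConv(chans, rng) if spec.use_scconv else None)
            downs.append(nn.Conv2d(chans, 2 * chans, 3, rng, stride=2))
            chans *= 2
            self.enc_channels.append(chans)
        self.enc_blocks = nn.ModuleList(enc_blocks)
        self.enc_scconv = nn.ModuleList([m for m in enc_scconv if m is not None])
        self._scconv_map = [m is not None for m in enc_scconv]
        self.downs = nn.ModuleList(downs)
        self.mid = ResBlock(chans, chans, rng, time_dim=td, dropout=spec.dropout)
        up_convs, dec_blocks = [], []
        for _ in range(spec.depth):
            up_convs.append(nn.Conv2d(chans, chans // 2, 3, rng))
            chans //= 2
            dec_blocks.append(ResBlock(2 * chans, chans, rng, time_dim=td, dropout=spec.dropout))
        self.up_convs = nn.ModuleList(up_convs)
        self.dec_blocks = nn.ModuleList(dec_blocks)
        self.out_norm = nn.GroupNorm(_gn_groups(c), c)
        self.out_conv = nn.Conv2d(c, 1, 3, rng, zero_init=True)

    def _time_embedding(self, t, batch, dtype):
        t = np.broadcast_to(np.atleast_1d(np.asarray(t, dtype=np.float64)), (batch,))
        emb = nn.sinusoidal_embedding(t, self.spec.time_embed_dim, dtype=dtype)
        h = ad.silu(self.time_mlp1(Tensor(emb)))
        return self.time_mlp2(h)

    def forward(self, x_t, condition, t):
        if x_t.shape != condition.shape:
            raise ConfigurationError("noisy input and condition shapes differ")
        _check_divisible(x_t.shape[2], x_t.shape[3], self.spec.depth)
        temb = self._time_embedding(t, x_t.shape[0], x_t.dtype)
        h = self.stem(ad.concat([x_t, condition], axis=1))
        skips = []
        sc_iter = iter(self.enc_scconv)
        for i, blk in enumerate(self.enc_blocks):
            h = blk(h, temb)
            if self._scconv_map[i]:
                h = next(sc_iter)(h)
            skips.append(h)
            h = ad.leaky_relu(self.downs[i](h), 0.2)
        h = self.mid(h, temb)
        for up, blk in zip(self.up_convs, self.dec_blocks):
            h = up(ad.upsample_nearest2x(h))
            h = blk(ad.concat([h, skips.pop()], axis=1), temb)
        delta = self.out_conv(ad.silu(self.out_norm(h)))
        base = _atanh(ad.clip(condition, -ATANH_CLIP, ATANH_CLIP))
        return ad.tanh(ad.add(delta, base))


class PatchDiscriminator(nn.Module):
    """Strided-conv PatchGAN; emits per-patch logits, scores after sigmoid.

    The conditional variant takes (candidate, x_t, condition, t): images are
    concatenated on channels and the timestep embedding is added as a
    per-channel bias after the first convolution.
    """

    def __init__(self, spec: DiscriminatorSpec, rng):
        super().__init__()
        self.spec = spec
        c = spec.base_channels
        in_ch = 3 if spec.conditional else 1
        self.stem = nn.Conv2d(in_ch, c, 4, rng, stride=2, padding=1)
        if spec.conditional:
            self.time_mlp = nn.Linear(spec.time_embed_dim, c, rng)
        layers = []
        chans = c
        for i in range(1, spec.n_layers):
            stride = 2 if i < spec.n_layers - 1 else 1
            layers.append(nn.Conv2d(chans, min(2 * chans, 8 * c), 4, rng,
                                    stride=stride, padding=1))
            chans = min(2 * chans, 8 * c)
        self.layers = nn.ModuleList(layers)
        self.head = nn.Conv2d(chans, 1, 4, rng, padding=1)

    def logits(self, x, x_t=None, condition=None, t=None):
        if self.spec.conditional:
            if x_t is None or condition is None or t is None:
                raise ConfigurationError("conditional discriminator needs (x_t, condition, t)")
            h = self.stem(ad.concat([x, x_t, condition], axis=1))
            tv = np.broadcast_to(np.atleast_1d(np.asarray(t, dtype=np.float64)),
                                 (x.shape[0],))
            emb = nn.sinusoidal_embedding(tv, self.spec.time_embed_dim, dtype=x.dtype)
            bias = self.time_mlp(Tensor(emb))
            h = ad.add(h, ad.reshape(bias, (x.shape[0], h.shape[1], 1, 1)))
        else:
            h = self.stem(x)
        h = ad.leaky_relu(h, 0.2)
        for layer in self.layers:
            h = ad.leaky_relu(layer(h), 0.2)
        return self.head(h)

    def forward(self, x, x_t=None, condition=None, t=None):
        return ad.sigmoid(self.logits(x, x_t, condition, t))


def build_matcher_generator(spec: GeneratorSpec, seed: int = 0) -> MatcherGenerator:
    return MatcherGenerator(spec, np.random.default_rng(seed))


def build_diffusive_generator(spec: GeneratorSpec, seed: int = 0) -> DiffusiveGenerator:
    return DiffusiveGenerator(spec, np.random.default_rng(seed))


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(spec, np.random.default_rng(seed))


@dataclass
class ScDiffModel:
    """The six-network bundle plus schedule and loss weights."""

    g_beta: MatcherGenerator
    g_beta_prime: MatcherGenerator
    d_beta: PatchDiscriminator
    d_beta_prime: PatchDiscriminator
    g_alpha: DiffusiveGenerator
    d_alpha: PatchDiscriminator
    schedule: NoiseSchedule
    loss_weights: LossWeights = field(default_factory=LossWeights)

    def networks(self):
        return {
            "g_beta": self.g_beta,
            "g_beta_prime": self.g_beta_prime,
            "d_beta": self.d_beta,
            "d_beta_prime": self.d_beta_prime,
            "g_alpha": self.g_alpha,
            "d_alpha": self.d_alpha,
        }

    def train(self, mode=True):
        for net in self.networks().values():
            net.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self):
        return {f"{name}.{k}": v
                for name, net in self.networks().items()
                for k, v in net.state_dict().items()}

    def load_state_dict(self, state):
        for name, net in self.networks().items():
            prefix = name + "."
            net.load_state_dict({k[len(prefix):]: v for k, v in state.items()
                                 if k.startswith(prefix)})


def build_model(schedule: NoiseSchedule,
                gen_spec: GeneratorSpec = GeneratorSpec(),
                diff_spec: GeneratorSpec | None = None,
                disc_spec: DiscriminatorSpec = DiscriminatorSpec(),
                loss_weights: LossWeights = LossWeights(),
                seed: int = 0) -> ScDiffModel:
    """Deterministically build all six networks from one seed."""
    if diff_spec is None:
        diff_spec = GeneratorSpec(
            base_channels=gen_spec.base_channels,
            depth=gen_spec.depth,
            use_scconv=True,
            dropout=gen_spec.dropout,
            time_embed_dim=gen_spec.time_embed_dim,
        )
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    cond_spec = DiscriminatorSpec(
        base_channels=disc_spec.base_channels,
        n_layers=disc_spec.n_layers,
        conditional=True,
        time_embed_dim=disc_spec.time_embed_dim,
    )
    return ScDiffModel(
        g_beta=build_matcher_generator(gen_spec, seeds[0]),
        g_beta_prime=build_matcher_generator(gen_spec, seeds[1]),
        d_beta=build_discriminator(disc_spec, seeds[2]),
        d_beta_prime=build_discriminator(disc_spec, seeds[3]),
        g_alpha=build_diffusive_generator(diff_spec, seeds[4]),
        d_alpha=build_discriminator(cond_spec, seeds[5]),
        schedule=schedule,
        loss_weights=loss_weights,
    )
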