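"""Joint training of the match and diffusive modules on unpaired slices.

One iteration:

1. Match forward: fake CBCT ``Gb(x_ct)``, cycled pCT ``Gb'(Gb(x_ct))``.
2. Draw a stride-aligned timestep t from {k, 2k, ..., T} and corrupt the
   pCT batch to ``x_t`` with the closed-form forward marginal.
3. Diffusive forward: clean-image estimate ``Ga(x_t, fake_cbct, t)`` and
   the reverse-transition candidate ``x_{t-k}`` from the k-step posterior.
4. Discriminator phase: update Db, Db' (non-saturating loss) and Da
   (non-saturating loss plus R1 gradient penalty at real ``x_{t-k}``).
5. Generator phase: update Gb, Gb' (adversarial + l1 cycle) and Ga
   (adversarial on the transition candidate + l1 cycle to the clean pCT).

Generator and discriminator parameters are optimized in alternating
phases, realizing the single total objective as two optimizer steps per
iteration.  The condition image passed to the diffusive module is detached
from the match-module graph; each module is driven by its own loss terms.
A non-finite loss raises :class:`DivergenceError` carrying the last-good
checkpoint path.  Optional global gradient-norm clipping (default on,
max-norm 1) guards against the runaway gradients large learning rates
provoke at high timesteps.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import losses as L
from . import nn
from .autodiff import Tensor
from .errors import ConfigurationError, DivergenceError
from .networks import (
    DiscriminatorSpec,
    GeneratorSpec,
    LossWeights,
    ScDiffModel,
    build_model,
)
from .schedule import build_linear_schedule, forward_marginal, posterior_coefficients

__all__ = [
    "TrainConfig",
    "PRESETS",
    "Trainer",
    "train_step",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    learning_rate: float = 2e-5
    adam_beta1: float = 0.5
    adam_beta2: float = 0.9
    batch_size: int = 4
    dropout: float = 0.0
    T: int = 1000
    k: int = 250
    theta_min: float = 1e-4
    theta_max: float = 0.02
    loss_weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    checkpoint_every: int = 1
    grad_clip: float | None = 1.0
    base_channels: int = 32
    depth: int = 3
    use_scconv: bool = True
    time_embed_dim: int = 64
    disc_channels: int = 32
    disc_layers: int = 3
    device_tag: str = "cpu"

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.T % self.k:
            raise ConfigurationError("T must be divisible by k")

    def build_schedule(self):
        return build_linear_schedule(self.T, self.theta_min, self.theta_max, self.k)

    def build_model(self) -> ScDiffModel:
        gen = GeneratorSpec(base_channels=self.base_channels, depth=self.depth,
                            dropout=self.dropout, time_embed_dim=self.time_embed_dim)
        diff = GeneratorSpec(base_channels=self.base_channels, depth=self.depth,
                             use_scconv=self.use_scconv, dropout=self.dropout,
                             time_embed_dim=self.time_embed_dim)
        disc = DiscriminatorSpec(base_channels=self.disc_channels,
                                 n_layers=self.disc_layers,
                                 time_embed_dim=self.time_embed_dim)
        return build_model(self.build_schedule(), gen_spec=gen, diff_spec=diff,
                           disc_spec=disc, loss_weights=self.loss_weights,
                           seed=self.seed)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "TrainConfig":
        d = json.loads(s)
        d["loss_weights"] = LossWeights(**d["loss_weights"])
        return cls(**d)


# Named presets.  "paper" carries the printed first-line settings; the
# printed discussion settings (higher learning rate, dropout 0.2) ship as
# "paper-discussion".  "desk" is the package's own scaled-down
# configuration for CPU-scale experiments on 64x64 synthetic slices.
PRESETS = {
    "paper": TrainConfig(),
    "paper-discussion": TrainConfig(learning_rate=5e-4, dropout=0.2),
    "desk": TrainConfig(epochs=10, learning_rate=2e-4, batch_size=2,
                        base_channels=16, depth=2, disc_channels=16,
                        disc_layers=2, time_embed_dim=32),
}

_TERMS = ("loss_g_beta", "loss_g_beta_prime", "loss_d_beta", "loss_d_beta_prime",
          "loss_g_alpha", "loss_d_alpha", "cycle_match", "cycle_diff",
          "loss_match", "loss_diff", "loss_cycle", "total")


class Trainer:
    """Holds the model, its optimizers and RNG; drives training iterations."""

    def __init__(self, model: ScDiffModel, config: TrainConfig):
        self.model = model
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        opt = lambda params: nn.Adam(params, lr=config.learning_rate,
                                     beta1=config.adam_beta1,
                                     beta2=config.adam_beta2,
                                     clip_norm=config.grad_clip)
        self.opt_match_g = opt(list(model.g_beta.parameters())
                               + list(model.g_beta_prime.parameters()))
        self.opt_match_d = opt(list(model.d_beta.parameters())
                               + list(model.d_beta_prime.parameters()))
        self.opt_diff_g = opt(list(model.g_alpha.parameters()))
        self.opt_diff_d = opt(list(model.d_alpha.parameters()))
        self.iteration = 0

    def optimizers(self):
        return {
            "match_g": self.opt_match_g, "match_d": self.opt_match_d,
            "diff_g": self.opt_diff_g, "diff_d": self.opt_diff_d,
        }

    def _zero_all(self):
        for net in self.model.networks().values():
            net.zero_grad()

    def step(self, batch_pct: np.ndarray, batch_cbct: np.ndarray) -> dict:
        """One joint iteration; returns the per-term loss breakdown."""
        model, w = self.model, self.model.loss_weights
        sched = model.schedule
        rng = self.rng
        dtype = nn.DTYPE

        x_ct = Tensor(np.ascontiguousarray(batch_pct, dtype=dtype))
        x_cbct = Tensor(np.ascontiguousarray(batch_cbct, dtype=dtype))

        # (1) match forward
        fake_cbct = model.g_beta(x_ct)
        cyc_ct = model.g_beta_prime(fake_cbct)
        cond = fake_cbct.detach()

        # (2) timestep and forward corruption
        n_steps = sched.num_sampling_steps
        t = int(sched.k * rng.integers(1, n_steps + 1))
        eps = rng.standard_normal(batch_pct.shape)
        x_t_np = forward_marginal(batch_pct, t, sched, eps).astype(dtype)
        x_t = Tensor(x_t_np)

        # (3) diffusive forward: clean estimate and transition candidate
        y0_hat = model.g_alpha(x_t, cond, t)
        c0, cxt, sigma = posterior_coefficients(t, sched)
        post_noise = rng.standard_normal(batch_pct.shape).astype(dtype)
        def candidate_from(y0):
            cand = ad.add(ad.mul(c0, y0), Tensor((cxt * x_t_np).astype(dtype)))
            if sigma > 0:
                cand = ad.add(cand, Tensor(sigma * post_noise))
            return cand

        # real sample of the transition target x_{t-k}
        eps2 = rng.standard_normal(batch_pct.shape)
        x_tk_real_np = forward_marginal(batch_pct, t - sched.k, sched, eps2).astype(dtype)

        # (4) discriminator phase
        self._zero_all()
        ld_beta = L.adv_disc_loss(model.d_beta(x_cbct), model.d_beta(fake_cbct.detach()))
        ld_beta_p = L.adv_disc_loss(model.d_beta_prime(x_ct), model.d_beta_prime(cyc_ct.detach()))
        cand_fake = candidate_from(y0_hat.detach())
        ld_alpha_adv = L.adv_disc_loss(
            model.d_alpha(Tensor(x_tk_real_np), x_t, cond, t),
            model.d_alpha(cand_fake, x_t, cond, t),
        )
        gp = L.gradient_penalty(
            lambda x: model.d_alpha.logits(x, x_t, cond, t),
            Tensor(x_tk_real_np, requires_grad=True),
            eta=w.eta,
        )
        ld_alpha = ad.add(ld_alpha_adv, gp)
        d_total = ad.add(ad.mul(w.lambda3, ad.add(ld_beta, ld_beta_p)),
                         ad.mul(w.lambda4, ld_alpha))
        if w.lambda3 > 0 or w.lambda4 > 0:
            d_total.backward()
        self.opt_match_d.step()
        self.opt_diff_d.step()

        # (5) generator phase
        self._zero_all()
        lg_beta = L.adv_gen_loss(model.d_beta(fake_cbct))
        lg_beta_p = L.adv_gen_loss(model.d_beta_prime(cyc_ct))
        cyc_m = L.cycle_loss(x_ct, cyc_ct, w.lambda1)
        g_match = ad.add(ad.mul(w.lambda3, ad.add(lg_beta, lg_beta_p)), cyc_m)
        g_match.backward()
        self.opt_match_g.step()

        self._zero_all()
        lg_alpha = L.adv_gen_loss(model.d_alpha(candidate_from(y0_hat), x_t, cond, t))
        cyc_d = L.cycle_loss(x_ct, y0_hat, w.lambda2)
        g_diff = ad.add(ad.mul(w.lambda4, lg_alpha), cyc_d)
        g_diff.backward()
        self.opt_diff_g.step()

        self.iteration += 1
        _, breakdown = L.total_loss(
            {
                "loss_g_beta": lg_beta, "loss_g_beta_prime": lg_beta_p,
                "loss_d_beta": ld_beta, "loss_d_beta_prime": ld_beta_p,
                "loss_g_alpha": lg_alpha, "loss_d_alpha": ld_alpha,
                "cycle_match": cyc_m, "cycle_diff": cyc_d,
            },
            w,
        )
        return breakdown


def train_step(model: ScDiffModel, batch_pct, batch_cbct, rng=None,
               trainer: Trainer | None = None, config: TrainConfig | None = None) -> dict:
    """One training iteration (thin functional wrapper around Trainer.step)."""
    if trainer is None:
        trainer = Trainer(model, config or TrainConfig())
    if rng is not None:
        trainer.rng = rng
    return trainer.step(np.asarray(batch_pct), np.asarray(batch_cbct))


def _batches(n_items, batch_size, rng):
    order = rng.permutation(n_items)
    for i in range(0, n_items - batch_size + 1, batch_size):
        yield order[i: i + batch_size]


def train(model: ScDiffModel, train_pct, train_cbct, config: TrainConfig,
          out_dir, max_iterations: int | None = None,
          resume_from=None, quiet: bool = True) -> Path:
    """Run the training loop; write checkpoints and a per-iteration loss CSV.

    ``train_pct`` / ``train_cbct`` are sequences of normalized (H, W)
    arrays in [-1, 1] (unpaired; they may have different lengths).
    Returns the path of the final checkpoint.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trainer = Trainer(model, config)
    start_epoch = 0
    if resume_from is not None:
        start_epoch = load_checkpoint(resume_from, model, trainer)
    pct = np.asarray([np.asarray(s, dtype=np.float32) for s in train_pct])[:, None]
    cbct = np.asarray([np.asarray(s, dtype=np.float32) for s in train_cbct])[:, None]
    if pct.shape[0] < config.batch_size or cbct.shape[0] < config.batch_size:
        raise ConfigurationError("fewer slices than one batch")

    history_path = out_dir / "history.csv"
    mode = "a" if (resume_from is not None and history_path.exists()) else "w"
    last_good = resume_from
    model.train()
    with open(history_path, mode, newline="") as fh:
        writer = csv.writer(fh)
        if mode == "w":
            writer.writerow(("iteration", "epoch") + _TERMS)
        done = False
        for epoch in range(start_epoch, config.epochs):
            cbct_order = trainer.rng.permutation(cbct.shape[0])
            for bi, idx in enumerate(_batches(pct.shape[0], config.batch_size, trainer.rng)):
                cb_idx = cbct_order[(bi * config.batch_size) % cbct.shape[0]:][: config.batch_size]
                if len(cb_idx) < config.batch_size:
                    cb_idx = cbct_order[: config.batch_size]
                try:
                    breakdown = trainer.step(pct[idx], cbct[cb_idx])
                except DivergenceError as exc:
                    raise DivergenceError(str(exc), checkpoint_path=last_good) from exc
                writer.writerow([trainer.iteration, epoch]
                                + [f"{breakdown[k]:.8f}" for k in _TERMS])
                if not quiet and trainer.iteration % 10 == 0:
                    print(f"iter {trainer.iteration} epoch {epoch} "
                          f"total {breakdown['total']:.4f}")
                if max_iterations is not None and trainer.iteration >= max_iterations:
                    done = True
                    break
            if (epoch + 1) % config.checkpoint_every == 0 or epoch == config.epochs - 1 or done:
                last_good = save_checkpoint(out_dir / f"checkpoint_{epoch:04d}.npz",
                                            model, trainer, epoch + 1)
            if done:
                break
    final = out_dir / "checkpoint_final.npz"
    save_checkpoint(final, model, trainer, config.epochs)
    return final


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: ScDiffModel, trainer: Trainer | None = None,
                    epoch: int = 0) -> Path:
    path = Path(path)
    arrays = {f"model.{k}": v for k, v in model.state_dict().items()}
    meta = {
        "epoch": epoch,
        "schedule": {"T": model.schedule.T, "k": model.schedule.k,
                     "theta_min": float(model.schedule.theta[0]),
                     "theta_max": float(model.schedule.theta[-1])},
        "loss_weights": asdict(model.loss_weights),
    }
    if trainer is not None:
        meta["config"] = json.loads(trainer.config.to_json())
        meta["iteration"] = trainer.iteration
        meta["rng_state"] = trainer.rng.bit_generator.state
        for name, opt in trainer.optimizers().items():
            st = opt.state_dict()
            arrays[f"opt.{name}.t"] = np.asarray(st["t"])
            for i, m in enumerate(st["m"]):
                arrays[f"opt.{name}.m.{i}"] = m
            for i, v in enumerate(st["v"]):
                arrays[f"opt.{name}.v.{i}"] = v
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


def load_checkpoint(path, model: ScDiffModel, trainer: Trainer | None = None) -> int:
    """Restore model (and trainer) state; returns the epoch to resume from."""
    with np.load(Path(path)) as f:
        meta = json.loads(bytes(f["meta"]).decode())
        state = {k[len("model."):]: f[k] for k in f.files if k.startswith("model.")}
        model.load_state_dict(state)
        if trainer is not None:
            trainer.iteration = int(meta.get("iteration", 0))
            if "rng_state" in meta:
                trainer.rng.bit_generator.state = meta["rng_state"]
            for name, opt in trainer.optimizers().items():
                tkey = f"opt.{name}.t"
                if tkey not in f.files:
                    continue
                n = len(opt.m)
                opt.load_state_dict({
                    "t": int(f[tkey]),
                    "m": [f[f"opt.{name}.m.{i}"] for i in range(n)],
                    "v": [f[f"opt.{name}.v.{i}"] for i in range(n)],
                })
    return int(meta.get("epoch", 0))
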