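"""Loss terms: non-saturating adversarial, R1 gradient penalty, l1 cycle.

Adversarial losses use the non-saturating form (generator maximizes
log D(fake) rather than minimizing log(1 - D(fake))).  The discriminator
of the diffusive module additionally carries an R1-style gradient penalty:
eta times the expected squared L2 norm of the input gradient of its
pre-sigmoid scores, evaluated at real samples.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ContractError, DivergenceError
from .networks import LossWeights

__all__ = [
    "adv_gen_loss",
    "adv_disc_loss",
    "gradient_penalty",
    "cycle_loss",
    "total_loss",
]

_EPS = 1e-12


def _as_tensor(x):
    return x if isinstance(x, Tensor) else ad.tensor(np.asarray(x, dtype=np.float64))


def _safe_log(scores):
    return ad.log(ad.clip(scores, _EPS, 1.0))


def adv_gen_loss(d_fake_scores) -> Tensor:
    """Non-saturating generator loss: mean of -log D(fake)."""
    s = _as_tensor(d_fake_scores)
    return ad.neg(ad.tmean(_safe_log(s)))


def adv_disc_loss(d_real_scores, d_fake_scores) -> Tensor:
    """mean(-log D(real)) + mean(-log(1 - D(fake)))."""
    r = _as_tensor(d_real_scores)
    f = _as_tensor(d_fake_scores)
    return ad.add(
        ad.neg(ad.tmean(_safe_log(r))),
        ad.neg(ad.tmean(_safe_log(ad.sub(1.0, f)))),
    )


def gradient_penalty(logits_fn, real_inputs, eta: float = 1.0) -> Tensor:
    """R1 penalty: eta * E_batch || d sum(logits) / d input ||^2 at real samples.

    ``logits_fn`` maps the (requires-grad) input tensor to pre-sigmoid
    scores.  The returned tensor is differentiable with respect to the
    discriminator parameters (grad-of-grad through the engine).
    """
    x = real_inputs
    if not isinstance(x, Tensor):
        x = ad.tensor(np.asarray(real_inputs, dtype=np.float64), requires_grad=True)
    if not x.requires_grad:
        raise ContractError("gradient_penalty input must require gradients")
    logits = logits_fn(x)
    g = ad.grad(ad.tsum(logits), x, create_graph=True)
    batch = x.shape[0] if x.ndim > 1 else 1
    sq = ad.tsum(ad.mul(g, g))
    return ad.mul(float(eta) / batch, sq)


def cycle_loss(a, b, lam: float = 1.0) -> Tensor:
    """Weighted l1 consistency: lam * mean |a - b|."""
    a = _as_tensor(a)
    b = _as_tensor(b)
    if a.shape != b.shape:
        raise ContractError(f"cycle_loss shape mismatch {a.shape} vs {b.shape}")
    return ad.mul(float(lam), ad.tmean(ad.absval(ad.sub(a, b))))


_MATCH_TERMS = ("loss_g_beta", "loss_g_beta_prime", "loss_d_beta", "loss_d_beta_prime")
_DIFF_TERMS = ("loss_g_alpha", "loss_d_alpha")
_CYCLE_TERMS = ("cycle_match", "cycle_diff")


def total_loss(parts: dict, weights: LossWeights):
    """Total objective: lambda3 * L_match + lambda4 * L_diff + L_cyc.

    ``parts`` maps term names to scalars (floats or Tensors).  Returns the
    scalar total and a float breakdown for logging.  Raises
    :class:`DivergenceError` on any non-finite part.
    """
    vals = {}
    for name in _MATCH_TERMS + _DIFF_TERMS + _CYCLE_TERMS:
        v = parts.get(name, 0.0)
        fv = float(v.data) if isinstance(v, Tensor) else float(v)
        if not np.isfinite(fv):
            raise DivergenceError(f"non-finite loss term {name} = {fv}")
        vals[name] = fv
    match = sum(vals[k] for k in _MATCH_TERMS)
    diff = sum(vals[k] for k in _DIFF_TERMS)
    cyc = sum(vals[k] for k in _CYCLE_TERMS)
    total = weights.lambda3 * match + weights.lambda4 * diff + cyc
    breakdown = dict(vals)
    breakdown.update(loss_match=match, loss_diff=diff, loss_cycle=cyc, total=total)
    return total, breakdown
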