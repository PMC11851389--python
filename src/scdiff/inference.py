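"""Artifact correction: run the diffusive generator over the reverse trajectory.

Only the diffusive generator is needed at inference.  Starting from unit
Gaussian noise at time T, each of the T/k strides asks the generator for a
clean-image estimate conditioned on the (real) CBCT slice, then moves to
time t-k through the k-step posterior; the terminal step is noiseless.
During training the condition was the match module's fake CBCT — at
inference the real CBCT slice takes its place.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .errors import ContractError
from .networks import ScDiffModel
from .schedule import posterior_step, sampling_times
from .volumes import DEFAULT_WINDOW, ImageVolume, IntensityWindow, denormalize, normalize

__all__ = ["correct_slice", "correct_volume"]


def _correct_normalized(cbct_norm: np.ndarray, model: ScDiffModel,
                        rng: np.random.Generator, call_counter=None) -> np.ndarray:
    """Reverse trajectory on one normalized slice; returns x_0 in [-1, 1]."""
    sched = model.schedule
    shape = (1, 1) + cbct_norm.shape
    cond = Tensor(np.ascontiguousarray(cbct_norm, dtype=nn.DTYPE).reshape(shape))
    x = rng.standard_normal(shape)
    with ad.no_grad():
        for t in sampling_times(sched):
            y0 = model.g_alpha(Tensor(x.astype(nn.DTYPE)), cond, t)
            if call_counter is not None:
                call_counter.append(t)
            noise = rng.standard_normal(shape)
            x = posterior_step(x, y0.data.astype(np.float64), t, sched, noise)
    return x[0, 0]


def correct_slice(cbct: ImageVolume, model: ScDiffModel, seed: int = 0,
                  window: IntensityWindow = DEFAULT_WINDOW,
                  call_counter=None) -> ImageVolume:
    """Correct one CBCT slice; deterministic given the seed."""
    data = cbct.data if isinstance(cbct, ImageVolume) else np.asarray(cbct)
    if data.ndim != 2:
        raise ContractError("correct_slice expects a single 2-D slice")
    if isinstance(cbct, ImageVolume):
        cbct.require_network_size()
    model.eval()
    rng = np.random.default_rng(seed)
    cbct_norm = normalize(data, window)
    x0 = _correct_normalized(cbct_norm, model, rng, call_counter)
    spacing = cbct.spacing if isinstance(cbct, ImageVolume) else None
    return denormalize(x0, window, modality_tag="scbct", spacing=spacing)


def _slice_seed(seed: int, data: np.ndarray) -> int:
    """Per-slice seed derived from the base seed and the slice content, so
    slice-wise results are independent of position in the stack."""
    import zlib

    digest = zlib.crc32(np.ascontiguousarray(data, dtype=np.float32).tobytes())
    return int(np.random.SeedSequence([seed, digest]).generate_state(1)[0] % (2**31))


def correct_volume(cbct_volume: ImageVolume, model: ScDiffModel, seed: int = 0,
                   window: IntensityWindow = DEFAULT_WINDOW) -> ImageVolume:
    """Slice-wise correction of a 3-D stack with per-slice derived seeds."""
    data = cbct_volume.data
    if data.ndim == 2:
        data = data[None]
    out = np.stack([
        correct_slice(
            ImageVolume(data[i], modality_tag="cbct"), model,
            seed=_slice_seed(seed, data[i]), window=window,
        ).data
        for i in range(data.shape[0])
    ])
    if cbct_volume.data.ndim == 2:
        out = out[0]
    return ImageVolume(out, spacing=cbct_volume.spacing, modality_tag="scbct")
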