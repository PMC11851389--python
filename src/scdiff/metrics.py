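"""Image-quality metrics (MAE, RMSE, PSNR, SSIM) and report helpers.

All metrics are evaluated in Hounsfield units after denormalization.  PSNR's
MAX and SSIM's dynamic range L default to the width of the evaluation
window (2000 HU for the default [-1000, 1000] window).  SSIM has two
modes: ``global`` computes the similarity index from whole-image moments
(c1 = (0.01 L)^2, c2 = (0.03 L)^2); ``windowed`` averages the local index
over sliding Gaussian windows (the common practice, via scikit-image).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .volumes import DEFAULT_WINDOW, ImageVolume, IntensityWindow

__all__ = [
    "MetricRecord",
    "mae",
    "rmse",
    "psnr",
    "ssim",
    "line_profile",
    "roi_stats",
    "evaluate_pairs",
]


def _arrays(a, b):
    a = a.data if isinstance(a, ImageVolume) else np.asarray(a, dtype=np.float64)
    b = b.data if isinstance(b, ImageVolume) else np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ContractError(f"shape mismatch {a.shape} vs {b.shape}")
    return a, b


def mae(a, b) -> float:
    """Mean absolute difference in HU."""
    a, b = _arrays(a, b)
    return float(np.mean(np.abs(a - b)))


def rmse(a, b) -> float:
    """Root mean squared difference in HU."""
    a, b = _arrays(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr(a, b, max_value: float = DEFAULT_WINDOW.width) -> float:
    """Peak signal-to-noise ratio, 10 log10(MAX^2 / MSE), in dB.

    Identical inputs return +inf (flagged sentinel rather than an error).
    """
    a, b = _arrays(a, b)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_value**2 / mse))


def ssim(a, b, dynamic_range: float = DEFAULT_WINDOW.width,
         mode: str = "global") -> float:
    """Structural similarity index.

    ``global`` evaluates the index once from whole-image means, variances
    and covariance; ``windowed`` is the sliding-window mean of the local
    index (11x11 Gaussian weights).
    """
    a, b = _arrays(a, b)
    if dynamic_range <= 0:
        raise ContractError("dynamic_range must be positive")
    if mode == "global":
        c1 = (0.01 * dynamic_range) ** 2
        c2 = (0.03 * dynamic_range) ** 2
        mu_a, mu_b = a.mean(), b.mean()
        var_a, var_b = a.var(), b.var()
        cov = ((a - mu_a) * (b - mu_b)).mean()
        return float(
            (2 * mu_a * mu_b + c1) * (2 * cov + c2)
            / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
        )
    if mode == "windowed":
        from skimage.metrics import structural_similarity

        return float(structural_similarity(
            a, b, data_range=dynamic_range, gaussian_weights=True,
            sigma=1.5, use_sample_covariance=False,
        ))
    raise ContractError(f"unknown SSIM mode {mode!r}")


def line_profile(img, axis: str, index: int) -> np.ndarray:
    """1-D HU sequence along a row (axis='row') or column (axis='col')."""
    data = img.data if isinstance(img, ImageVolume) else np.asarray(img)
    if data.ndim != 2:
        raise ContractError("line_profile expects a 2-D slice")
    if axis == "row":
        if not 0 <= index < data.shape[0]:
            raise ContractError(f"row {index} out of bounds")
        return data[index, :].copy()
    if axis == "col":
        if not 0 <= index < data.shape[1]:
            raise ContractError(f"column {index} out of bounds")
        return data[:, index].copy()
    raise ContractError("axis must be 'row' or 'col'")


def roi_stats(img, roi_box) -> dict:
    """HU summary of a rectangular ROI (r0, r1, c0, c1), half-open."""
    data = img.data if isinstance(img, ImageVolume) else np.asarray(img)
    r0, r1, c0, c1 = roi_box
    if not (0 <= r0 < r1 <= data.shape[-2] and 0 <= c0 < c1 <= data.shape[-1]):
        raise ContractError(f"ROI {roi_box} out of bounds for {data.shape}")
    roi = data[..., r0:r1, c0:c1]
    if roi.size == 0:
        raise ContractError("empty ROI")
    q = np.percentile(roi, [5, 25, 50, 75, 95])
    return {
        "mean": float(roi.mean()),
        "sd": float(roi.std()),
        "q05": float(q[0]), "q25": float(q[1]), "median": float(q[2]),
        "q75": float(q[3]), "q95": float(q[4]),
        "n": int(roi.size),
    }


@dataclass(frozen=True)
class MetricRecord:
    subject_id: str
    mae: float
    rmse: float
    psnr: float
    ssim: float
    n_slices: int

    def __post_init__(self):
        if self.mae > self.rmse + 1e-9:
            raise ContractError("MAE cannot exceed RMSE")
        if self.ssim > 1.0 + 1e-9:
            raise ContractError("SSIM cannot exceed 1")


def evaluate_pairs(pred_set, ref_set, window: IntensityWindow = DEFAULT_WINDOW,
                   subject_ids=None, ssim_mode: str = "global") -> pd.DataFrame:
    """Per-subject metric table plus a mean row.

    ``pred_set`` / ``ref_set`` are aligned sequences of slices (2-D
    ImageVolumes or arrays).  ``subject_ids`` groups slices by subject;
    default is one subject for all slices.  Slice metrics are averaged
    within subject (PSNR computed per slice then averaged).
    """
    if len(pred_set) != len(ref_set):
        raise ContractError("pred and ref sets differ in length")
    if subject_ids is None:
        subject_ids = ["all"] * len(pred_set)
    rows = {}
    for pred, ref, sid in zip(pred_set, ref_set, subject_ids):
        rows.setdefault(sid, []).append((
            mae(pred, ref),
            rmse(pred, ref),
            psnr(pred, ref, window.width),
            ssim(pred, ref, window.width, mode=ssim_mode),
        ))
    records = []
    for sid, vals in rows.items():
        arr = np.asarray(vals)
        records.append(MetricRecord(str(sid), *[float(v) for v in arr.mean(axis=0)],
                                    n_slices=len(vals)))
    df = pd.DataFrame([r.__dict__ for r in records])
    mean_row = df[["mae", "rmse", "psnr", "ssim"]].mean()
    df.loc[len(df)] = {
        "subject_id": "mean",
        "mae": mean_row["mae"], "rmse": mean_row["rmse"],
        "psnr": mean_row["psnr"], "ssim": mean_row["ssim"],
        "n_slices": int(df["n_slices"].sum()),
    }
    return df


def to_markdown_table(df: pd.DataFrame) -> str:
    """Render the metric table in the usual per-patient report layout."""
    header = "| Subject | MAE (HU) | RMSE (HU) | PSNR (dB) | SSIM | Slices |"
    sep = "|---|---|---|---|---|---|"
    lines = [header, sep]
    for _, row in df.iterrows():
        lines.append(
            f"| {row['subject_id']} | {row['mae']:.3f} | {row['rmse']:.3f} "
            f"| {row['psnr']:.3f} | {row['ssim']:.3f} | {int(row['n_slices'])} |"
        )
    return "\n".join(lines)
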