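"""End-to-end desk-scale experiment: simulate, train, correct, evaluate.

The default experiment mirrors the study design at reduced scale: unpaired
training sets of 100 pCT and 100 CBCT slices (64x64, from disjoint
synthetic subjects), a held-out paired test set of 20 slices, the "desk"
training preset (tiny networks, T = 1000, k = 250), and the standard
metric table comparing uncorrected CBCT and corrected sCBCT against the
ground-truth pCT.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import correct_slice
from .metrics import evaluate_pairs
from .phantom import build_unpaired_dataset
from .training import PRESETS, train
from .volumes import DEFAULT_WINDOW, normalize

__all__ = ["run_demo", "DEMO_SIZES"]

DEMO_SIZES = {
    # n_subjects, slices_per_subject, image size, test slices, iterations
    "full": dict(n_subjects=5, slices_per_subject=50, size=64, n_test=20,
                 max_iterations=350),
    "fast": dict(n_subjects=3, slices_per_subject=4, size=32, n_test=2,
                 max_iterations=3),
}


def run_demo(out_dir: Path, seed: int = 0, fast: bool = False,
             max_iterations: int | None = None) -> pd.DataFrame:
    """Run the full loop; returns the metric table (CBCT and sCBCT vs pCT)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sizes = DEMO_SIZES["fast" if fast else "full"]
    iters = sizes["max_iterations"] if max_iterations is None else max_iterations

    ds = build_unpaired_dataset(
        sizes["n_subjects"], sizes["slices_per_subject"],
        size=sizes["size"], seed=seed,
    )
    ds.save(out_dir / "data")

    cfg = replace(PRESETS["desk"], seed=seed)
    model = cfg.build_model()
    pct = [normalize(v, DEFAULT_WINDOW) for v in ds.train_pct]
    cbct = [normalize(v, DEFAULT_WINDOW) for v in ds.train_cbct]
    train(model, pct, cbct, cfg, out_dir / "train", max_iterations=iters)

    n_test = min(sizes["n_test"], len(ds.test_pct))
    test_pct = ds.test_pct[:n_test]
    test_cbct = ds.test_cbct[:n_test]
    scbct = [correct_slice(v, model, seed=seed + i) for i, v in enumerate(test_cbct)]

    df_cbct = evaluate_pairs(test_cbct, test_pct, subject_ids=["cbct"] * n_test)
    df_scbct = evaluate_pairs(scbct, test_pct, subject_ids=["scbct"] * n_test)
    report = pd.concat([df_cbct[df_cbct.subject_id == "cbct"],
                        df_scbct[df_scbct.subject_id == "scbct"]],
                       ignore_index=True)
    report.to_csv(out_dir / "report.csv", index=False)
    (out_dir / "report.json").write_text(json.dumps({
        row.subject_id: {"mae": row.mae, "rmse": row.rmse,
                         "psnr": row.psnr, "ssim": row.ssim}
        for row in report.itertuples()
    }, indent=2))
    np.savez(out_dir / "example_slices.npz",
             cbct=test_cbct[0].data.astype(np.float32),
             scbct=scbct[0].data.astype(np.float32),
             pct=test_pct[0].data.astype(np.float32))
    return report
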