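"""Image-quality metrics: MSE, PSNR and (global) SSIM.

SSIM is evaluated globally — one mean/variance/covariance triple per image —
with stabilizers ``c1 = (0.01)^2`` and ``c2 = (0.02)^2`` on the [0, 1]
intensity scale.  Sample statistics (ddof=1) are used, matching windowed
reference implementations when their window spans the whole image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

CHANNEL_NAMES = ("mu_a", "mu_s_prime")


@dataclass(frozen=True)
class SSIMConfig:
    """Stabilizing constants of the SSIM formula (on the [0,1] scale)."""

    const_1: float = 0.01**2
    const_2: float = 0.02**2

    def __post_init__(self) -> None:
        if self.const_1 <= 0 or self.const_2 <= 0:
            raise ValueError("SSIM constants must be positive")


def _check_pair(x_true: np.ndarray, x_rec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x_true = np.asarray(x_true, dtype=float)
    x_rec = np.asarray(x_rec, dtype=float)
    if x_true.shape != x_rec.shape:
        raise ValueError(f"shape mismatch: {x_true.shape} vs {x_rec.shape}")
    return x_true, x_rec


def mse(x_true: np.ndarray, x_rec: np.ndarray) -> float:
    """Mean squared pixel difference."""
    x_true, x_rec = _check_pair(x_true, x_rec)
    return float(np.mean((x_true - x_rec) ** 2))


def psnr(x_true: np.ndarray, x_rec: np.ndarray) -> float:
    """Peak signal-to-noise ratio, dB:  10 log10(max(x_true)^2 / MSE).

    Returns ``inf`` for identical images; raises if the reference image has
    no positive peak.
    """
    x_true, x_rec = _check_pair(x_true, x_rec)
    peak = float(x_true.max())
    if peak <= 0:
        raise ValueError("reference image must have a positive maximum")
    err = mse(x_true, x_rec)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / err))


def ssim(x_true: np.ndarray, x_rec: np.ndarray, cfg: SSIMConfig | None = None) -> float:
    """Global structural similarity between two [0,1]-scaled images."""
    cfg = cfg or SSIMConfig()
    x_true, x_rec = _check_pair(x_true, x_rec)
    n = x_true.size
    mt, mr = x_true.mean(), x_rec.mean()
    ddof = 1 if n > 1 else 0
    vt = x_true.var(ddof=ddof)
    vr = x_rec.var(ddof=ddof)
    cov = ((x_true - mt) * (x_rec - mr)).sum() / max(n - 1, 1)
    c1, c2 = cfg.const_1, cfg.const_2
    return float(
        ((2 * mt * mr + c1) * (2 * cov + c2)) / ((mt**2 + mr**2 + c1) * (vt + vr + c2))
    )


def evaluate_split(
    model_outputs: Sequence[np.ndarray],
    ground_truths: Sequence[np.ndarray],
    cfg: SSIMConfig | None = None,
    normalize: bool = True,
    label: str = "",
) -> pd.DataFrame:
    """Per-sample metrics for a split; one row per (sample, channel).

    Inputs are (2, H, W) stacks (channel 0 = mu_a, channel 1 = mu_s').  With
    ``normalize=True`` each channel pair is mapped to [0, 1] by the ground
    truth's min-max range before SSIM/PSNR (physical-unit MSE is reported
    alongside).
    """
    if len(model_outputs) == 0:
        raise ValueError("empty split")
    if len(model_outputs) != len(ground_truths):
        raise ValueError("outputs and ground truths differ in length")
    rows = []
    for s, (out, gt) in enumerate(zip(model_outputs, ground_truths)):
        out = np.asarray(out, dtype=float)
        gt = np.asarray(gt, dtype=float)
        for c, name in enumerate(CHANNEL_NAMES):
            t, r = gt[c], out[c]
            mse_phys = mse(t, r)
            if normalize:
                lo, hi = float(t.min()), float(t.max())
                scale = hi - lo if hi > lo else 1.0
                t = (t - lo) / scale
                r = (r - lo) / scale
            rows.append(
                {
                    "sample_id": s,
                    "channel": name,
                    "mse": mse(t, r),
                    "mse_physical": mse_phys,
                    "psnr_db": psnr(t, r),
                    "ssim": ssim(t, r, cfg),
                    "method": label,
                }
            )
    return pd.DataFrame(rows)


def aggregate(report: pd.DataFrame) -> dict:
    """Mean/min/max of each metric per channel."""
    out: dict = {}
    for name, grp in report.groupby("channel"):
        out[name] = {
            m: {
                "mean": float(grp[m].mean()),
                "min": float(grp[m].min()),
                "max": float(grp[m].max()),
            }
            for m in ("mse", "psnr_db", "ssim")
        }
    return out


def save_report(report: pd.DataFrame, csv_path, json_path=None) -> None:
    """CSV of per-sample rows plus an optional JSON aggregate summary."""
    report.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(aggregate(report), fh, indent=2)
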