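"""Cube-vs-cube quality metrics: PSNR, SAM and SSIM.

All three compare a reconstructed hyperspectral cube against a
reference on the same X×Y×C grid:

* PSNR — 10·log10(range² / MSE) over all voxels, in dB; identical
  cubes report ``inf``.
* SAM — the spectral angle mapper: the mean over pixels of the angle
  (radians) between the per-pixel spectra; invariant to per-pixel
  positive rescaling, so it isolates spectral shape errors from
  intensity errors.
* SSIM — structural similarity with the universal defaults (11×11
  Gaussian window, sigma 1.5, K1=0.01, K2=0.03), computed per band and
  averaged across bands.

:func:`evaluate_cubes` aggregates the three metrics over a test set
into per-image rows plus mean ± sd, and :func:`paired_ttest` compares
two methods image-by-image.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

__all__ = ["psnr", "sam", "ssim_cube", "evaluate_cubes", "paired_ttest"]


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    return pred, truth


def psnr(pred: np.ndarray, truth: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB (``inf`` for identical cubes)."""
    pred, truth = _check_pair(pred, truth)
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((pred - truth) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(data_range**2 / mse)


def sam(pred: np.ndarray, truth: np.ndarray, eps: float = 1e-12, degrees: bool = False) -> float:
    """Spectral angle mapper: mean per-pixel angle between spectra.

    Radians by default; 0 for identical (or per-pixel positively
    rescaled) cubes.
    """
    pred, truth = _check_pair(pred, truth)
    if pred.ndim != 3 or pred.shape[2] < 2:
        raise ValueError("SAM requires X×Y×C cubes with C >= 2")
    dot = np.sum(pred * truth, axis=2)
    norms = np.linalg.norm(pred, axis=2) * np.linalg.norm(truth, axis=2)
    cosang = np.clip(dot / (norms + eps), -1.0, 1.0)
    angles = np.arccos(cosang)
    out = float(np.mean(angles))
    return float(np.degrees(out)) if degrees else out


def ssim_cube(pred: np.ndarray, truth: np.ndarray, data_range: float = 1.0) -> float:
    """Mean per-band structural similarity (Gaussian 11×11 window)."""
    pred, truth = _check_pair(pred, truth)
    if pred.ndim != 3:
        raise ValueError("ssim_cube expects X×Y×C cubes")
    if min(pred.shape[:2]) < 11:
        raise ValueError("image smaller than the 11×11 SSIM window")
    vals = [
        structural_similarity(
            truth[:, :, c],
            pred[:, :, c],
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
        )
        for c in range(pred.shape[2])
    ]
    return float(np.mean(vals))


def evaluate_cubes(
    preds: Sequence[np.ndarray],
    truths: Sequence[np.ndarray],
    data_range: float = 1.0,
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-image metric table with an aggregate mean ± sd row.

    Returns a DataFrame with columns (image, ssim, psnr, sam); the last
    two rows hold the across-image mean and standard deviation (PSNR is
    averaged per image, matching a mean ± sd presentation).
    """
    if len(preds) != len(truths):
        raise ValueError("preds and truths must have equal length")
    if len(preds) == 0:
        raise ValueError("empty evaluation set")
    names = list(names) if names is not None else [f"image_{i}" for i in range(len(preds))]
    rows = [
        {
            "image": name,
            "ssim": ssim_cube(p, t, data_range),
            "psnr": psnr(p, t, data_range),
            "sam": sam(p, t),
        }
        for name, p, t in zip(names, preds, truths)
    ]
    df = pd.DataFrame(rows)
    agg = df[["ssim", "psnr", "sam"]]
    df = pd.concat(
        [
            df,
            pd.DataFrame(
                [
                    {"image": "mean", **agg.mean().to_dict()},
                    {"image": "sd", **agg.std(ddof=1).to_dict()},
                ]
            ),
        ],
        ignore_index=True,
    )
    return df


def paired_ttest(scores_a: Sequence[float], scores_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test over per-image scores of two methods.

    Returns (t statistic, p value)."""
    from scipy.stats import ttest_rel

    res = ttest_rel(np.asarray(scores_a, float), np.asarray(scores_b, float))
    return float(res.statistic), float(res.pvalue)
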