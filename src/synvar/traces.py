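"""Calcium-trace normalization and response-shape clustering.

Raw ROI fluorescence is high-pass filtered (moving-baseline subtraction),
converted to dF/F with a mean-augmented denominator that stabilizes
near-zero baselines, trial-averaged, resampled to a common rate, z-scored,
and clustered under the correlation distance to expose the diversity of
response time courses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.cluster import KMeans

from .synthetic import TraceSet

__all__ = [
    "delta_f_over_f",
    "zscore_traces",
    "cluster_traces",
]

BACKGROUND_LABEL = "background"


def _background_mask(ts: TraceSet, n_samples: int) -> np.ndarray:
    t = np.arange(n_samples) / ts.sampling_rate
    mask = np.zeros(n_samples, dtype=bool)
    for (label, start, end) in ts.epochs:
        if label == BACKGROUND_LABEL:
            mask |= (t >= start) & (t < end)
    return mask


def delta_f_over_f(
    ts: TraceSet,
    highpass_period_frames: int | None = 150,
    target_rate_hz: float | None = 10.0,
) -> TraceSet:
    """Normalize fluorescence to dF/F and resample to a common rate.

    Per ROI: (1) optional high-pass as subtraction of a centred moving
    median over ``highpass_period_frames`` frames; (2) baseline F0 = mean
    over all background-stimulus epochs; (3) dF/F = (F - F0)/(F0 + Fmean)
    where Fmean is the mean of the full raw trace, guarding against
    near-zero baselines; (4) average over equal-length trials; (5) linear
    interpolation to ``target_rate_hz``.
    """
    F = ts.F
    n_rois, n_total = F.shape
    if ts.n_trials < 1 or n_total % ts.n_trials:
        raise ValueError("trace length must divide into equal trials")
    trial_len = n_total // ts.n_trials
    bg = _background_mask(ts, trial_len)
    if not bg.any():
        raise ValueError("no background epochs defined; F0 is undefined")

    f_mean = F.mean(axis=1)
    if highpass_period_frames:
        baseline = ndimage.median_filter(
            F, size=(1, int(highpass_period_frames)), mode="nearest"
        )
        work = F - baseline
    else:
        work = F.copy()

    trials = work.reshape(n_rois, ts.n_trials, trial_len)
    avg = trials.mean(axis=1)
    f0 = avg[:, bg].mean(axis=1)
    denom = f0 + f_mean
    bad = np.isclose(denom, 0.0)
    if bad.any():
        raise ValueError(
            f"F0 + Fmean is zero for ROI(s) {np.flatnonzero(bad).tolist()}"
        )
    dff = (avg - f0[:, None]) / denom[:, None]

    rate = ts.sampling_rate
    if target_rate_hz and target_rate_hz != rate:
        t_old = np.arange(trial_len) / rate
        t_new = np.arange(0.0, t_old[-1] + 1e-12, 1.0 / target_rate_hz)
        dff = np.stack([np.interp(t_new, t_old, row) for row in dff])
        rate = target_rate_hz
    return TraceSet(dff, sampling_rate=rate, epochs=ts.epochs, n_trials=1)


def zscore_traces(ts: TraceSet) -> TraceSet:
    """Z-score each trace: subtract its mean, divide by its (population) std."""
    F = ts.F
    std = F.std(axis=1, ddof=0)
    bad = np.flatnonzero(std == 0)
    if len(bad):
        raise ValueError(f"zero-variance trace(s): ROI {bad.tolist()}")
    z = (F - F.mean(axis=1, keepdims=True)) / std[:, None]
    return TraceSet(z, sampling_rate=ts.sampling_rate, epochs=ts.epochs,
                    n_trials=ts.n_trials)


def cluster_traces(
    ts: TraceSet, k: int = 6, seed: int = 0, n_restarts: int = 10
) -> tuple[pd.Series, np.ndarray]:
    """K-means under correlation distance; labels and cluster-mean traces.

    Correlation distance d(u, v) = 1 - corr(u, v) is, on z-scored traces,
    proportional to squared Euclidean distance, so standard k-means on the
    z-scored rows minimizes it directly.  Input traces are re-z-scored
    internally, making the clustering invariant to per-trace affine gain.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if ts.n_rois < k:
        raise ValueError(f"fewer traces ({ts.n_rois}) than clusters ({k})")
    z = zscore_traces(ts).F
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(z)
    means = np.stack([z[labels == c].mean(axis=0) for c in range(k)])
    return pd.Series(labels, name="cluster"), means
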