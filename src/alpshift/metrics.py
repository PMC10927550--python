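"""Presence-absence and presence-only model evaluation metrics."""

from __future__ import annotations

import numpy as np
from scipy import stats


def tss(pred: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    """True skill statistic (sensitivity + specificity - 1) at a threshold.

    Predictions >= threshold count as presence. Requires both classes.
    """
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("TSS requires both presence and absence labels")
    hit = pred >= threshold
    sens = np.mean(hit[labels])
    spec = np.mean(~hit[~labels])
    return float(sens + spec - 1.0)


def max_tss_threshold(pred: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Threshold maximizing TSS over the grid of unique predicted values.

    Ties are broken toward the smallest threshold achieving the maximum.
    Returns (threshold, tss_at_threshold).
    """
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("maxTSS requires both presence and absence labels")
    cand = np.unique(pred)
    best_t, best_v = cand[0], -np.inf
    for t in cand:
        v = tss(pred, labels, t)
        if v > best_v + 1e-15:
            best_t, best_v = t, v
    return float(best_t), float(best_v)


def boyce(
    pred_presence: np.ndarray,
    pred_background: np.ndarray,
    n_windows: int = 10,
) -> float | None:
    """Continuous Boyce index.

    Moving windows of width (range / n_windows) are stepped across the
    suitability range; each window's predicted-to-expected ratio is the
    share of presences falling in it divided by the share of background
    values. The index is the Spearman rank correlation between P/E and the
    window midpoint. Returns None when undefined (constant predictions or
    fewer than two valid windows).
    """
    pres = np.asarray(pred_presence, dtype=float)
    back = np.asarray(pred_background, dtype=float)
    lo, hi = back.min(), back.max()
    if hi <= lo or len(np.unique(back)) < 2:
        return None
    width = (hi - lo) / n_windows
    n_steps = 10 * n_windows  # overlapping windows, step = width/10
    step = (hi - lo - width) / max(n_steps - 1, 1)
    mids, ratios = [], []
    for i in range(n_steps):
        a = lo + i * step
        b = a + width
        p = np.mean((pres >= a) & (pres <= b))
        e = np.mean((back >= a) & (back <= b))
        if e > 0:
            mids.append((a + b) / 2)
            ratios.append(p / e)
    if len(mids) < 2 or len(set(ratios)) < 2:
        return None
    rho = stats.spearmanr(mids, ratios).statistic
    return None if np.isnan(rho) else float(rho)
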