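"""Greedy multi-feature spatial prioritization.

Cells are removed one at a time, always the cell whose loss hurts the
remaining feature representation least; a cell's rank is the fraction of
cells removed at or before it (1 = removed last = highest priority). Two
marginal-loss rules are provided: core-area (CAZ — a cell is worth the
single worst-off feature's weighted remaining share, protecting features
with little distribution left) and additive benefit (ABF — a cell is
worth the summed concave representation benefit across all features,
favouring local richness hotspots). Expansion mode locks an existing
protected-area network as highest priority and ranks only the free cells.

No batch removal is used: cells are removed strictly one at a time, which
is exact and affordable at the coarse-grid sizes this package targets.
Ties break toward the lowest cell index, making runs reproducible and
directly comparable to a from-scratch reference ranker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FeatureMatrix:
    """Cells x features non-negative values with per-feature weights."""

    values: np.ndarray  # (n_cells, n_features)
    weights: np.ndarray | None = None
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D (cells x features)")
        if (self.values < 0).any():
            raise ValueError("feature values must be >= 0")
        n_feat = self.values.shape[1]
        if self.weights is None:
            self.weights = np.ones(n_feat)
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights <= 0).any():
            raise ValueError("feature weights must be > 0")
        if self.feature_names is None:
            self.feature_names = [f"f{j}" for j in range(n_feat)]
        totals = self.values.sum(axis=0)
        if (totals <= 0).any():
            bad = [self.feature_names[j] for j in np.nonzero(totals <= 0)[0]]
            raise ValueError(f"all-zero feature(s): {bad}")

    @property
    def totals(self) -> np.ndarray:
        return self.values.sum(axis=0)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class PriorityRank:
    """Per-cell priority rank in (0, 1]; 1 = last removed = highest priority."""

    rank: np.ndarray
    algorithm: str  # CAZ | ABF
    mode: str = "selection"  # selection | expansion
    pa_mask: np.ndarray | None = None
    removal_order: np.ndarray | None = None  # cell indices in removal order

    def top_fraction_mask(self, top: float, free_only: bool = True) -> np.ndarray:
        """Cells in the top ``top`` fraction; over free (non-PA) cells by default."""
        if self.pa_mask is not None and free_only:
            free = ~self.pa_mask.astype(bool)
            n_top = int(round(top * free.sum()))
            order = np.argsort(self.rank)  # ascending; highest rank last
            chosen = [i for i in order[::-1] if free[i]][:n_top]
            mask = np.zeros(len(self.rank), dtype=bool)
            mask[chosen] = True
            return mask
        n_top = int(round(top * len(self.rank)))
        thresh_idx = np.argsort(self.rank)[::-1][:n_top]
        mask = np.zeros(len(self.rank), dtype=bool)
        mask[thresh_idx] = True
        return mask


def _greedy_rank(
    F: FeatureMatrix,
    delta_fn,
    strata: np.ndarray,
    algorithm: str,
    mode: str,
    pa_mask: np.ndarray | None,
) -> PriorityRank:
    """Iterative removal within ascending strata (all stratum-0 cells first)."""
    n = F.n_cells
    remaining = np.ones(n, dtype=bool)
    rem_totals = F.totals.copy()
    order = np.empty(n, dtype=int)
    pos = 0
    for stratum in np.unique(strata):
        eligible = strata == stratum
        while (remaining & eligible).any():
            idx = np.nonzero(remaining & eligible)[0]
            delta = delta_fn(F.values[idx], rem_totals, F.weights, F.totals)
            pick = idx[int(np.argmin(delta))]  # argmin takes first = lowest index
            rem_totals = rem_totals - F.values[pick]
            remaining[pick] = False
            order[pos] = pick
            pos += 1
    rank = np.empty(n)
    rank[order] = (np.arange(n) + 1) / n
    return PriorityRank(rank, algorithm, mode, pa_mask, removal_order=order)


def _caz_delta(vals, rem_totals, weights, totals):
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(rem_totals > 0, vals / rem_totals, 0.0)
    return (weights * q).max(axis=1)


def _make_abf_delta(z: float):
    def _abf_delta(vals, rem_totals, weights, totals):
        R = np.where(totals > 0, rem_totals / totals, 0.0)
        qp = vals / totals
        before = np.power(np.clip(R, 0.0, None), z)
        after = np.power(np.clip(R - qp, 0.0, None), z)
        return ((before - after) * weights).sum(axis=1)

    return _abf_delta


def apply_mode(
    n_cells: int, pa_mask: np.ndarray | None, mode: str
) -> tuple[np.ndarray, np.ndarray | None]:
    """Removal strata for a ranking mode.

    selection: one stratum (unconstrained). expansion: all free cells are
    removed before any protected cell, so every PA cell outranks every
    free cell.
    """
    if mode == "selection" or pa_mask is None:
        return np.zeros(n_cells, dtype=int), None if mode == "selection" else pa_mask
    pa = np.asarray(pa_mask).astype(bool).ravel()
    if len(pa) != n_cells:
        raise ValueError("PA mask does not conform to the feature matrix")
    if mode == "expansion":
        if pa.all():
            raise ValueError("PA mask covers every cell; nothing to expand")
        return pa.astype(int), pa
    raise ValueError(f"unknown mode {mode!r}")


def rank_caz(
    F: FeatureMatrix, pa_mask: np.ndarray | None = None, mode: str = "selection"
) -> PriorityRank:
    """Core-area ranking: remove the cell minimizing max_j w_j a_ij / remaining_j."""
    strata, pa = apply_mode(F.n_cells, pa_mask, mode)
    return _greedy_rank(F, _caz_delta, strata, "CAZ", mode, pa)


def rank_abf(
    F: FeatureMatrix,
    z: float = 0.25,
    pa_mask: np.ndarray | None = None,
    mode: str = "selection",
) -> PriorityRank:
    """Additive-benefit ranking with concave exponent ``z``.

    delta_i = sum_j w_j [R_j^z - (R_j - a_ij/A_j)^z] with R_j the remaining
    fraction of feature j's original total.
    """
    if z <= 0:
        raise ValueError("z must be > 0")
    strata, pa = apply_mode(F.n_cells, pa_mask, mode)
    return _greedy_rank(F, _make_abf_delta(z), strata, "ABF", mode, pa)


def performance_curves(
    rank: PriorityRank,
    F: FeatureMatrix,
    fractions: np.ndarray | None = None,
    extra_layers: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Cumulative representation of every feature in the top fraction f.

    representation_j(f) = sum over cells with rank > 1 - f of a_ij / A_j.
    ``extra_layers`` maps names to per-cell vectors (branch intensities,
    binary ranges, rarity-weighted layers) given the same treatment.
    Returns tidy (fraction, feature, representation) rows plus a
    "mean_species" summary feature.
    """
    if fractions is None:
        fractions = np.linspace(0.0, 1.0, 21)
    layers = {
        name: F.values[:, j] for j, name in enumerate(F.feature_names)
    }
    if extra_layers:
        layers.update({k: np.asarray(v, dtype=float) for k, v in extra_layers.items()})
    rows = []
    for f in fractions:
        sel = rank.rank > 1.0 - f + 1e-12
        reps = []
        for name, vals in layers.items():
            total = vals.sum()
            rep = float(vals[sel].sum() / total) if total > 0 else np.nan
            rows.append((float(f), name, rep))
            if name in F.feature_names:
                reps.append(rep)
        rows.append((float(f), "mean_species", float(np.mean(reps))))
    return pd.DataFrame(rows, columns=["fraction", "feature", "representation"])


def expansion_overlap(
    ranks: dict[str, PriorityRank],
    pa_mask: np.ndarray,
    top: float = 0.20,
    region: np.ndarray | None = None,
    elevation_stratum: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Cross-scenario overlap of top-fraction reserve expansions.

    Marks each scenario's top ``top`` fraction of free (non-PA) cells,
    counts per cell how many scenarios marked it, and defines expanded PAs
    as cells marked by >= 2 scenarios. The summary reports the protected
    fraction before (mask) and after (mask plus expansion), overall and —
    when region/elevation-stratum labels are given — per (region,
    stratum) zone.
    """
    pa = np.asarray(pa_mask).astype(bool).ravel()
    marks = []
    for name, r in ranks.items():
        if r.mode != "expansion":
            raise ValueError(f"rank {name!r} is not an expansion-mode ranking")
        if len(r.rank) != len(pa):
            raise ValueError("rank/mask grids are inconsistent")
        marks.append(r.top_fraction_mask(top, free_only=True))
    counts = np.sum(marks, axis=0).astype(int)
    expanded = counts >= 2
    after = pa | expanded
    summary = {
        "top": top,
        "n_scenarios": len(ranks),
        "protected_fraction_before": float(pa.mean()),
        "protected_fraction_after": float(after.mean()),
        "overlap_counts": {int(k): int(v) for k, v in zip(*np.unique(counts, return_counts=True))},
    }
    if region is not None and elevation_stratum is not None:
        zones = []
        region = np.asarray(region).ravel()
        stratum = np.asarray(elevation_stratum).ravel()
        for rg in np.unique(region):
            for stz in np.unique(stratum):
                sel = (region == rg) & (stratum == stz)
                if not sel.any():
                    continue
                zones.append(
                    {
                        "region": rg,
                        "stratum": stz,
                        "n_cells": int(sel.sum()),
                        "protected_before": float(pa[sel].mean()),
                        "protected_after": float(after[sel].mean()),
                        "share_of_expansion": float(expanded[sel].sum() / max(expanded.sum(), 1)),
                    }
                )
        summary["zones"] = zones
    return counts, summary
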