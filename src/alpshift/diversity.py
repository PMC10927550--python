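"""Multifaceted diversity, endemism, rarity and uniqueness weights.

All metrics operate on a stack of per-species intensity maps (one value
per coarse cell per species) plus a phylogeny and a functional
dendrogram. Diversity uses Hill numbers of order q = 1 — the exponential
of Shannon entropy for the taxonomic case and its effective-branch-length
extension for trees. Endemism concentrates range-size-weighted species
(WE) or branches (PE/FE) into cells; rarity combines a species' tree
distinctiveness with its geographic restrictedness.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .trees import FeatureTree


def hill_q1_taxonomic(intensities: np.ndarray) -> float:
    """Taxonomic diversity: exp(Shannon entropy) of the within-cell shares."""
    x = np.asarray(intensities, dtype=float)
    if (x < 0).any():
        raise ValueError("intensities must be >= 0")
    total = x.sum()
    if total <= 0:
        return np.nan
    p = x[x > 0] / total
    return float(np.exp(-np.sum(p * np.log(p))))


def hill_q1_tree(intensities: np.ndarray, tree: FeatureTree) -> float:
    """Phylogenetic/functional diversity at q = 1 as effective branch length.

    With branch shares a_b (summed tip shares below branch b) and mean
    path length T = sum(L_b a_b), the value is
    T * exp(-sum_b (L_b a_b / T) ln a_b).
    """
    x = np.asarray(intensities, dtype=float)
    if len(x) != len(tree.species):
        raise ValueError("intensity vector does not match tree tips")
    total = x.sum()
    if total <= 0:
        return np.nan
    p = x / total
    a = tree.membership @ p
    La = tree.lengths * a
    T = La.sum()
    if T <= 0:
        return np.nan
    pos = a > 0
    return float(T * np.exp(-np.sum((La[pos] / T) * np.log(a[pos]))))


def relative_metric(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of the OLS fit y ~ 1 + x + x^2 over occupied cells.

    NaN cells (in either input) are excluded and propagate as NaN
    residuals.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    if ok.sum() < 4:
        raise ValueError("need at least 4 occupied cells")
    xv = x[ok]
    if np.ptp(xv) == 0:
        raise ValueError("regressor is constant")
    X = np.column_stack([np.ones(ok.sum()), xv, xv**2])
    beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
    out = np.full(y.shape, np.nan)
    out[ok] = y[ok] - X @ beta
    return out


def _branch_cell_intensity(
    A: np.ndarray, tree: FeatureTree, branch_combine: str
) -> np.ndarray:
    """(cells x branches) intensity; max (union-like) or sum over descendant tips."""
    if branch_combine == "max":
        # einsum-free loop over branches keeps memory bounded
        out = np.empty((A.shape[0], len(tree.lengths)))
        for b, row in enumerate(tree.membership):
            out[:, b] = A[:, row].max(axis=1) if row.any() else 0.0
        return out
    if branch_combine == "sum":
        return A @ tree.membership.T
    raise ValueError("branch_combine must be 'max' or 'sum'")


def endemism(
    A: np.ndarray, tree: FeatureTree | None = None, branch_combine: str = "max"
) -> np.ndarray:
    """Weighted (WE) or phylogenetic/functional (PE/FE) endemism per cell.

    ``A`` is (cells x species) intensity. WE_i = sum_s a_is / A_s. With a
    tree, branches replace species: each branch's per-cell intensity is
    the max (default; union of descendant ranges) or sum over its
    descendant tips, weighted by branch length over the branch total.
    Cell sums conserve: sum(WE) = S and sum(PE) = total branch length.
    """
    A = np.asarray(A, dtype=float)
    if tree is None:
        totals = A.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("species with zero total range")
        return (A / totals).sum(axis=1)
    B = _branch_cell_intensity(A, tree, branch_combine)
    totals = B.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("branch with zero total range")
    return (B / totals) @ tree.lengths


def distinctiveness_restrictedness(
    A: np.ndarray, tree: FeatureTree
) -> tuple[np.ndarray, np.ndarray]:
    """Species-level distinctiveness D and restrictedness R.

    D_s = mean pairwise patristic distance to all other species, rescaled
    by the maximum pairwise distance; R_s = 1 - occupied cells / total
    cells.
    """
    if len(tree.species) < 2:
        raise ValueError("distinctiveness undefined for a single species")
    D = tree.pairwise_distances()
    n = D.shape[0]
    mean_d = (D.sum(axis=1)) / (n - 1)
    dmax = D.max()
    dist = mean_d / dmax if dmax > 0 else np.zeros(n)
    occ = (np.asarray(A) > 0).sum(axis=0)
    R = 1.0 - occ / A.shape[0]
    return dist, R


def rarity(A: np.ndarray, tree: FeatureTree) -> np.ndarray:
    """Per-cell rarity: intensity-weighted mean of D_s * R_s over present species."""
    dist, R = distinctiveness_restrictedness(A, tree)
    score = dist * R
    A = np.asarray(A, dtype=float)
    w = A.sum(axis=1)
    out = np.full(A.shape[0], np.nan)
    occ = w > 0
    out[occ] = (A[occ] @ score) / w[occ]
    return out


def uniqueness_weights(
    phylo: FeatureTree, functional: FeatureTree, A_current: np.ndarray
) -> pd.Series:
    """Per-species prioritization weight: sum of the two rarity facets.

    Each facet (distinctiveness x restrictedness on the phylogeny and on
    the functional tree) is normalized to mean 1 over species before
    summing, so neither facet's scale dominates. Degenerate trees (all
    distances zero) fall back to a uniform facet with a warning.
    """
    weights = np.zeros(len(phylo.species))
    for tree in (phylo, functional):
        dist, R = distinctiveness_restrictedness(A_current, tree)
        facet = dist * R
        if facet.sum() <= 0:
            warnings.warn(f"degenerate {tree.kind} facet; using uniform weights")
            facet = np.ones_like(facet)
        weights = weights + facet / facet.mean()
    w = pd.Series(weights, index=phylo.species)
    if (w <= 0).any():
        w = w + 1e-12
    return w


def cell_metrics(
    A: np.ndarray,
    phylo: FeatureTree,
    functional: FeatureTree,
) -> pd.DataFrame:
    """All per-cell metrics for one scenario: TD/PD/FD, rPD/rFD, WE/PE/FE, rPE/rFE, PR/FR."""
    A = np.asarray(A, dtype=float)
    n_cells = A.shape[0]
    td = np.array([hill_q1_taxonomic(A[i]) for i in range(n_cells)])
    pd_ = np.array([hill_q1_tree(A[i], phylo) for i in range(n_cells)])
    fd = np.array([hill_q1_tree(A[i], functional) for i in range(n_cells)])
    we = endemism(A)
    pe = endemism(A, phylo)
    fe = endemism(A, functional)
    out = pd.DataFrame(
        {
            "TD": td,
            "PD": pd_,
            "FD": fd,
            "rPD": relative_metric(pd_, td),
            "rFD": relative_metric(fd, td),
            "WE": we,
            "PE": pe,
            "FE": fe,
            "rPE": relative_metric(pe, we),
            "rFE": relative_metric(fe, we),
            "PR": rarity(A, phylo),
            "FR": rarity(A, functional),
        }
    )
    out.index.name = "cell"
    return out
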