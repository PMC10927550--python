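"""Observer-bias covariates and environmental bias correction (EBC).

Presence-only records inherit the spatial habits of their collectors:
more records near roads and towns, and more in well-surveyed countries.
Two complementary corrections are applied before model fitting: (1) bias
covariates (observation density, distance to roads, distance to cities)
entered into the point-process model so the fitted observer effect can be
zeroed out at projection time, and (2) environmental bias correction,
which resamples a species' records so their distribution across
environmental clusters matches each cluster's areal share.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .grids import CLIMATE_LAYERS, SOIL_LAYERS, GridSpec, LayerStack, distance_to
from .synthetic import OccurrenceTable


@dataclass
class BiasCovariates:
    """sqrt-transformed observation density and road/city proximity rasters."""

    grid: GridSpec
    obsdens: np.ndarray  # sqrt(all-species record count per cell)
    droad: np.ndarray  # sqrt(metres to nearest road cell)
    dcity: np.ndarray  # sqrt(metres to nearest city cell)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"OBSDENS": self.obsdens, "DROAD": self.droad, "DCITY": self.dcity}

    def zeroed(self) -> "BiasCovariates":
        z = np.zeros(self.grid.shape)
        return BiasCovariates(self.grid, z, z, z)


@dataclass
class EnvClustering:
    """Partition of grid cells into K environmental clusters."""

    k: int
    labels: np.ndarray  # per-cell cluster id in 1..K (0 where nodata)
    areal_share: np.ndarray  # length K, sums to 1 over valid cells

    def __post_init__(self) -> None:
        present = np.unique(self.labels[self.labels > 0])
        if len(present) and (present.min() < 1 or present.max() > self.k):
            raise ValueError("cluster ids must lie in 1..K")


def build_bias_covariates(
    occ: OccurrenceTable, roads: np.ndarray, cities: np.ndarray, grid: GridSpec
) -> BiasCovariates:
    """Observer-bias covariates on the fine grid.

    Observation density is the all-species record count per cell (sum
    aggregation), sqrt-transformed. Road/city distances are centre-to-centre
    Euclidean, 0 inside a road/city cell, sqrt-transformed.
    """
    roads = np.asarray(roads).astype(bool)
    cities = np.asarray(cities).astype(bool)
    if roads.shape != grid.shape or cities.shape != grid.shape:
        raise ValueError("road/city layers do not conform to the grid")
    counts = np.zeros(grid.shape)
    if occ.n_records:
        row, col = grid.xy_to_rowcol(occ.records["x"].to_numpy(), occ.records["y"].to_numpy())
        np.add.at(counts, (row, col), occ.records["multiplicity"].to_numpy().astype(float))
    return BiasCovariates(
        grid,
        obsdens=np.sqrt(counts),
        droad=np.sqrt(distance_to(roads, grid.cell_size)),
        dcity=np.sqrt(distance_to(cities, grid.cell_size)),
    )


def check_bias_correlations(bias: BiasCovariates, stack: LayerStack, limit: float = 0.3) -> list[str]:
    """Warn (never fail) when a bias covariate correlates with climate/soil at |r| >= limit."""
    msgs = []
    for bname, bvals in bias.as_dict().items():
        for ename in CLIMATE_LAYERS + SOIL_LAYERS:
            b = bvals.ravel()
            if b.std() == 0:
                continue
            r = np.corrcoef(b, stack.layers[ename].ravel())[0, 1]
            if abs(r) >= limit:
                msg = f"bias covariate {bname} vs {ename}: |r| = {abs(r):.2f} >= {limit}"
                warnings.warn(msg)
                msgs.append(msg)
    return msgs


def filter_prevalence_and_cap(
    occ: OccurrenceTable,
    grid: GridSpec,
    min_pixels: int = 30,
    cap: int = 10000,
    seed: int = 0,
) -> tuple[OccurrenceTable, list[str]]:
    """Drop low-prevalence species and cap record counts.

    Species occupying fewer than ``min_pixels`` distinct fine cells are
    removed; species with more than ``cap`` records are subsampled to
    exactly ``cap`` uniformly without replacement. Returns the filtered
    table and the retained-species list.
    """
    rng = np.random.default_rng(seed)
    df = occ.records
    if not len(df):
        return OccurrenceTable(df.copy(), occ.provenance), []
    row, col = grid.xy_to_rowcol(df["x"].to_numpy(), df["y"].to_numpy())
    cell = row * grid.n_cols + col
    keep_frames = []
    retained: list[str] = []
    for sp, idx in df.groupby("species", sort=True).groups.items():
        idx = np.asarray(idx)
        if len(np.unique(cell[df.index.get_indexer(idx)])) < min_pixels:
            continue
        retained.append(sp)
        sub = df.loc[idx]
        if len(sub) > cap:
            take = rng.choice(len(sub), size=cap, replace=False)
            sub = sub.iloc[np.sort(take)]
        keep_frames.append(sub)
    out = (
        pd.concat(keep_frames, ignore_index=True)
        if keep_frames
        else df.iloc[0:0].reset_index(drop=True)
    )
    return OccurrenceTable(out, occ.provenance), retained


def cluster_environment(stack: LayerStack, k: int, seed: int = 0) -> EnvClustering:
    """K-means partition of cells in z-scored climate + soil space.

    Degenerate (constant) environments collapse to one effective cluster;
    ties in assignment are broken by cell index via the deterministic
    seeded k-means run.
    """
    valid = stack.valid().ravel()
    n_valid = int(valid.sum())
    if k < 2:
        raise ValueError("K must be >= 2")
    if k > n_valid:
        raise ValueError(f"K={k} exceeds the number of non-nodata cells ({n_valid})")
    feats = []
    for name in CLIMATE_LAYERS + SOIL_LAYERS:
        v = stack.layers[name].ravel()[valid]
        sd = v.std()
        feats.append((v - v.mean()) / (sd if sd > 0 else 1.0))
    X = np.column_stack(feats)
    if np.allclose(X, X[0]):
        labels_valid = np.zeros(n_valid, dtype=int)  # one effective cluster
    else:
        km = KMeans(n_clusters=k, n_init=1, random_state=seed)
        labels_valid = km.fit_predict(X)
    labels = np.zeros(stack.grid.n_cells, dtype=int)
    labels[valid] = labels_valid + 1
    share = np.bincount(labels_valid, minlength=k).astype(float)
    return EnvClustering(k, labels.reshape(stack.grid.shape), share / share.sum())


def ebc_resample(
    occ: OccurrenceTable,
    clustering: EnvClustering,
    grid: GridSpec,
    max_dup: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    target: str = "areal",
) -> OccurrenceTable:
    """Environmental bias correction for a single species.

    Compares the species' per-cluster record share against the cluster
    areal share with a chi-squared goodness-of-fit test at ``alpha``. If
    biased, resamples toward per-cluster targets round(total x share):
    over-represented clusters are subsampled without replacement,
    under-represented ones duplicated with replacement via the
    multiplicity column, with the per-record duplication factor capped at
    ``max_dup`` (any deficit beyond the cap stays uncorrected). Unbiased
    species pass through unchanged with provenance "raw".

    ``target`` = "areal" (cluster areal share, default) or "uniform".
    """
    df = occ.records
    if not len(df):
        raise ValueError("species has zero records")
    if df["species"].nunique() > 1:
        raise ValueError("ebc_resample expects a single species' records")
    k = clustering.k
    share = clustering.areal_share if target == "areal" else np.full(k, 1.0 / k)
    row, col = grid.xy_to_rowcol(df["x"].to_numpy(), df["y"].to_numpy())
    labels = clustering.labels[row, col]
    if (labels == 0).any():
        raise ValueError("some records fall on nodata cells")
    effective = np.nonzero(clustering.areal_share > 0)[0] + 1
    if len(effective) < 2:
        return OccurrenceTable(df.copy(), "raw")

    total = int(df["multiplicity"].sum())
    obs = np.bincount(labels, weights=df["multiplicity"], minlength=k + 1)[1:]
    exp = total * share
    use = share > 0
    with np.errstate(invalid="ignore"):
        chi2 = np.sum((obs[use] - exp[use]) ** 2 / exp[use])
    dof = int(use.sum()) - 1
    pval = stats.chi2.sf(chi2, dof) if dof > 0 else 1.0
    targets = np.round(total * share).astype(int)
    if pval >= alpha or np.array_equal(obs.astype(int), targets):
        return OccurrenceTable(df.copy(), "raw")

    rng = np.random.default_rng(seed)
    out_frames = []
    for c in range(1, k + 1):
        sub = df[labels == c]
        if not len(sub):
            continue  # cannot invent records for an unsampled cluster
        tgt = targets[c - 1]
        n = len(sub)
        if tgt <= 0:
            continue
        if n >= tgt:
            take = np.sort(rng.choice(n, size=tgt, replace=False))
            picked = sub.iloc[take].copy()
            picked["multiplicity"] = 1
        else:
            base, extra = divmod(tgt, n)
            base = min(base, max_dup)
            mult = np.full(n, base)
            if base < max_dup and extra > 0:
                bump = rng.choice(n, size=extra, replace=False)
                mult[bump] += 1
            picked = sub.copy()
            picked["multiplicity"] = mult
        out_frames.append(picked)
    out = pd.concat(out_frames, ignore_index=True)
    return OccurrenceTable(out, "bias-corrected")
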