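"""Penalized point-process species distribution models.

Presence-only records are modelled as an inhomogeneous Poisson point
process whose intensity (expected records per unit area) is log-linear in
climate, soil, land-cover and observer-bias covariates. The likelihood
integral is approximated with Berman-Turner quadrature, coefficients are
fitted by elastic-net-penalized Poisson regression, models are evaluated
by spatial-block cross-validation against independent elevational test
ranges (TSS and continuous Boyce index), thresholded at maxTSS, projected
to scenario stacks with the bias covariates zeroed, ensembled across
replicates, and aggregated to the coarse grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bias import BiasCovariates
from .grids import CLIMATE_LAYERS, SOIL_LAYERS, GridSpec, LayerStack, block_aggregate
from .metrics import boyce, max_tss_threshold, tss
from .synthetic import ElevationalRange, OccurrenceTable

PRESENCE_EPS_FRACTION = 1e-9  # share of total area carried by each presence point


@dataclass
class QuadratureScheme:
    """Berman-Turner quadrature: weighted presence and background points."""

    grid: GridSpec
    quad_cells: np.ndarray  # flat cell indices of quadrature points
    quad_weights: np.ndarray  # area represented per point, m^2
    presence_cells: np.ndarray
    presence_weights: np.ndarray
    presence_multiplicity: np.ndarray
    trace: list[tuple[int, float]] = field(default_factory=list)  # (n_quad, loglik)

    def __post_init__(self) -> None:
        if (self.quad_weights <= 0).any() or (self.presence_weights <= 0).any():
            raise ValueError("quadrature weights must be positive")

    @property
    def total_weight(self) -> float:
        return float(
            self.quad_weights.sum()
            + (self.presence_weights * self.presence_multiplicity).sum()
        )


@dataclass
class SpeciesModel:
    """A fitted point-process SDM for one species and one LC variant."""

    species: str
    lc_variant: str  # which categorical land-cover layer the dummies encode
    coef: pd.Series  # named coefficients incl. intercept
    alpha: float  # elastic-net mixing (1 = lasso, 0 = ridge)
    lam: float  # selected penalty strength (0 = unpenalized)
    scaler: dict  # per-column (mean, sd) used to standardize the design
    lc_reference: int  # reference land-cover category (most frequent)
    lc_levels: list[int] = field(default_factory=list)
    fold_tss: list[float] = field(default_factory=list)
    fold_boyce: list[float | None] = field(default_factory=list)
    threshold: float | None = None  # maxTSS threshold on the rescaled (0,1) intensity
    rescale_q99: float | None = None  # 99th pct of the current intensity map
    retained: bool = True

    @property
    def mean_tss(self) -> float | None:
        return float(np.mean(self.fold_tss)) if self.fold_tss else None

    @property
    def mean_boyce(self) -> float | None:
        vals = [b for b in self.fold_boyce if b is not None]
        return float(np.mean(vals)) if vals else None


@dataclass
class ScenarioCube:
    """Per-species, per-scenario intensity and binary rasters."""

    species: str
    scenario: str  # "current" or "<horizon>-SSP<ssp>"
    intensity: np.ndarray
    binary: np.ndarray
    mode: str = "unlimited"  # unlimited | limited | none
    resolution: str = "fine"

    def __post_init__(self) -> None:
        if (self.intensity < 0).any():
            raise ValueError("intensity must be non-negative")
        if not np.isin(np.unique(self.binary), [0, 1]).all():
            raise ValueError("binary layer must be 0/1")

    @property
    def intensity_and_absence(self) -> np.ndarray:
        return self.intensity * self.binary


def apply_retention_rule(mean_tss: float | None, mean_boyce: float | None, cutoff: float = 0.3) -> bool:
    """A model is dropped iff both TSS and Boyce fall below the cutoff.

    A missing (undefined) Boyce cannot rescue a poor TSS on its own: it is
    treated as below-cutoff for this rule.
    """
    t = mean_tss if mean_tss is not None else -1.0
    b = mean_boyce if mean_boyce is not None else -1.0
    return not (t < cutoff and b < cutoff)


# ---------------------------------------------------------------------------
# design matrix


def _design_columns(
    stack: LayerStack,
    bias: BiasCovariates | None,
    lc_variant: str,
    lc_reference: int,
    lc_levels: list[int],
) -> pd.DataFrame:
    cols = {}
    for name in CLIMATE_LAYERS + SOIL_LAYERS:
        cols[name] = stack.layers[name].ravel()
    lc = stack.categorical_layers[lc_variant].ravel()
    for lvl in lc_levels:
        if lvl == lc_reference:
            continue
        cols[f"{lc_variant}_{lvl}"] = (lc == lvl).astype(float)
    if bias is not None:
        for name, vals in bias.as_dict().items():
            cols[name] = vals.ravel()
    return pd.DataFrame(cols)


def build_design(
    stack: LayerStack,
    bias: BiasCovariates | None,
    lc_variant: str = "LC",
    scaler: dict | None = None,
    lc_reference: int | None = None,
    lc_levels: list[int] | None = None,
) -> tuple[pd.DataFrame, dict, int, list[int]]:
    """Standardized per-cell design matrix (no intercept column).

    Continuous columns are z-scored; a stored ``scaler`` reapplies the
    calibration-period scaling to future stacks. Land cover enters as
    one-hot dummies against the most frequent (reference) class.
    """
    lc = stack.categorical_layers[lc_variant].ravel()
    if lc_levels is None:
        lc_levels = sorted(np.unique(lc).tolist())
    if lc_reference is None:
        lc_reference = int(np.bincount(lc).argmax())
    X = _design_columns(stack, bias, lc_variant, lc_reference, lc_levels)
    if scaler is None:
        scaler = {}
        for c in X.columns:
            if c.startswith(lc_variant + "_"):
                scaler[c] = (0.0, 1.0)
            else:
                sd = X[c].std() or 1.0
                scaler[c] = (float(X[c].mean()), float(sd))
    for c in X.columns:
        m, s = scaler.get(c, (0.0, 1.0))
        X[c] = (X[c] - m) / s
    return X, scaler, lc_reference, lc_levels


# ---------------------------------------------------------------------------
# quadrature


def _ppm_rows(
    quad: QuadratureScheme, X_cells: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Berman-Turner response z, weights w and design rows for all points."""
    cells = np.concatenate([quad.presence_cells, quad.quad_cells])
    w = np.concatenate([quad.presence_weights, quad.quad_weights])
    mult = np.concatenate(
        [quad.presence_multiplicity, np.ones(len(quad.quad_cells))]
    )
    y = np.concatenate(
        [np.ones(len(quad.presence_cells)), np.zeros(len(quad.quad_cells))]
    )
    z = y / w
    rows = X_cells[cells]
    return z, w * mult, rows


def _weighted_poisson_loglik(z, w, eta) -> float:
    lam = np.exp(eta)
    return float(np.sum(w * (z * eta - lam)))


def _fit_glm(z, w, rows, lam: float, alpha: float, maxiter: int = 200) -> np.ndarray:
    Xd = sm.add_constant(rows, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(z, Xd, family=sm.families.Poisson(), var_weights=w)
        if lam == 0.0:
            res = model.fit(maxiter=maxiter)
            params = res.params
        else:
            pen = np.ones(Xd.shape[1])
            pen[0] = 0.0  # never penalize the intercept
            res = model.fit_regularized(alpha=lam * pen, L1_wt=alpha, maxiter=maxiter)
            params = res.params
    if not np.all(np.isfinite(params)):
        raise RuntimeError("point-process fit diverged (non-finite coefficients)")
    return np.asarray(params)


def make_quadrature(
    grid: GridSpec,
    occ: OccurrenceTable,
    n_quad: int,
    seed: int,
) -> QuadratureScheme:
    """Uniform-random quadrature with Berman-Turner area weights.

    Each quadrature point represents (total area - presence share) /
    n_quad; each presence carries a tiny epsilon area so the weight sum
    equals the study area exactly.
    """
    rng = np.random.default_rng(seed)
    quad_cells = rng.integers(0, grid.n_cells, n_quad)
    row, col = grid.xy_to_rowcol(occ.records["x"].to_numpy(), occ.records["y"].to_numpy())
    pres_cells = row * grid.n_cols + col
    mult = occ.records["multiplicity"].to_numpy().astype(float)
    eps = PRESENCE_EPS_FRACTION * grid.total_area
    pres_w = np.full(len(pres_cells), eps)
    quad_w = np.full(n_quad, (grid.total_area - (pres_w * mult).sum()) / n_quad)
    return QuadratureScheme(grid, quad_cells, quad_w, pres_cells, pres_w, mult)


def choose_quadrature(
    stack: LayerStack,
    occ: OccurrenceTable,
    bias: BiasCovariates | None = None,
    seed: int = 0,
    n0: int = 1000,
    tol: float = 0.01,
    max_doublings: int = 8,
    lc_variant: str = "LC",
) -> QuadratureScheme:
    """Double the quadrature count until the fitted log-likelihood stabilizes.

    Starting from ``n0`` uniform points, the count doubles (n0, 2n0, ...)
    with an unpenalized point-process fit at each size, until the relative
    change in maximized log-likelihood falls below ``tol``; warns and
    returns the largest scheme after ``max_doublings`` without convergence.
    """
    X, scaler, ref, levels = build_design(stack, bias, lc_variant)
    X_cells = X.to_numpy()
    prev_ll = None
    trace: list[tuple[int, float]] = []
    n = n0
    scheme = None
    for i in range(max_doublings + 1):
        scheme = make_quadrature(stack.grid, occ, n, seed)
        z, w, rows = _ppm_rows(scheme, X_cells)
        params = _fit_glm(z, w, rows, lam=0.0, alpha=0.5)
        ll = _weighted_poisson_loglik(z, w, sm.add_constant(rows, has_constant="add") @ params)
        trace.append((n, ll))
        if prev_ll is not None and abs(ll - prev_ll) / max(abs(prev_ll), 1e-12) < tol:
            scheme.trace = trace
            return scheme
        prev_ll = ll
        n *= 2
    warnings.warn(
        f"quadrature log-likelihood did not stabilize after {max_doublings} doublings"
    )
    scheme.trace = trace
    return scheme


# ---------------------------------------------------------------------------
# spatial blocks


def spatial_blocks(grid: GridSpec, n_blocks: int = 10) -> np.ndarray:
    """Checkerboard of rectangles: a 2 x (n_blocks/2) tiling, per-cell block id."""
    if n_blocks % 2:
        raise ValueError("n_blocks must be even")
    half = n_blocks // 2
    rows = np.minimum(np.arange(grid.n_rows) * 2 // grid.n_rows, 1)
    cols = np.minimum(np.arange(grid.n_cols) * half // grid.n_cols, half - 1)
    return rows[:, None] * half + cols[None, :]


def blocks_to_folds(block_id: np.ndarray, n_folds: int = 5) -> np.ndarray:
    """Pair the two block rows into folds by opposite corners."""
    half = int(block_id.max()) + 1 - n_folds
    top = block_id < half
    fold = np.where(top, block_id, (2 * half - 1) - block_id)
    return fold % n_folds


# ---------------------------------------------------------------------------
# fitting


def fit_ppm(
    occ: OccurrenceTable,
    quad: QuadratureScheme,
    stack: LayerStack,
    bias: BiasCovariates | None,
    alpha: float = 0.5,
    lam_grid: tuple[float, ...] = (1e-2, 1e-3, 1e-4),
    lc_variant: str = "LC",
    n_blocks: int = 10,
    n_folds: int = 5,
    seed: int = 0,
    penalize: bool = True,
    species: str | None = None,
) -> SpeciesModel:
    """Fit one elastic-net point-process model.

    The penalty strength is selected by 5-fold cross-validated predictive
    deviance on contiguous spatial blocks, then the model is refitted on
    all points at the selected strength. ``penalize=False`` gives the
    unpenalized maximum-likelihood fit (used for parameter recovery and
    quadrature selection checks).
    """
    if occ.n_records == 0:
        raise ValueError("cannot fit a model to zero records")
    if species is None:
        species = str(occ.records["species"].iloc[0]) if len(occ.records) else "unknown"
    if len(np.unique(quad.presence_cells)) < 2:
        raise ValueError("degenerate input: all presences fall in a single cell")
    X, scaler, ref, levels = build_design(stack, bias, lc_variant)
    Xc = X.to_numpy()
    # drop constant (collinear) columns, e.g. absent land-cover classes
    keep = Xc.std(axis=0) > 0
    if not keep.any():
        raise ValueError("degenerate design: all columns constant")
    colnames = [c for c, k in zip(X.columns, keep) if k]
    Xc = Xc[:, keep]

    z, w, rows = _ppm_rows(quad, Xc)
    lam = 0.0
    if penalize and len(lam_grid) > 1:
        block = spatial_blocks(quad.grid, n_blocks)
        fold_of_cell = blocks_to_folds(block, n_folds).ravel()
        cells = np.concatenate([quad.presence_cells, quad.quad_cells])
        fold = fold_of_cell[cells]
        scores = []
        for l in lam_grid:
            dev = 0.0
            for f in range(n_folds):
                tr = fold != f
                if tr.all() or not tr.any():
                    continue
                try:
                    # a coarse iteration budget suffices to rank penalty strengths
                    params = _fit_glm(z[tr], w[tr], rows[tr], l, alpha, maxiter=40)
                except RuntimeError:
                    dev = np.inf
                    break
                eta = sm.add_constant(rows[~tr], has_constant="add") @ params
                dev += -2.0 * _weighted_poisson_loglik(z[~tr], w[~tr], eta)
            scores.append(dev)
        lam = lam_grid[int(np.argmin(scores))]
    elif penalize:
        lam = lam_grid[0]
    params = _fit_glm(z, w, rows, lam, alpha)
    coef = pd.Series(params, index=["intercept"] + colnames)
    return SpeciesModel(
        species=species,
        lc_variant=lc_variant,
        coef=coef,
        alpha=alpha,
        lam=lam,
        scaler=scaler,
        lc_reference=ref,
        lc_levels=levels,
    )


def predict_intensity(
    model: SpeciesModel,
    stack: LayerStack,
    bias: BiasCovariates | None = None,
    scaler_stack: LayerStack | None = None,
) -> np.ndarray:
    """Per-cell intensity (expected records per cell) under a stack.

    ``bias=None`` sets every bias covariate to 0 (the projection
    convention removing fitted observer effects).
    """
    if bias is None:
        bias = BiasCovariates(
            stack.grid,
            np.zeros(stack.grid.shape),
            np.zeros(stack.grid.shape),
            np.zeros(stack.grid.shape),
        )
    X, _, _, _ = build_design(
        stack,
        bias,
        model.lc_variant,
        scaler=model.scaler,
        lc_reference=model.lc_reference,
        lc_levels=model.lc_levels,
    )
    eta = np.full(stack.grid.n_cells, model.coef["intercept"])
    for name, b in model.coef.items():
        if name == "intercept":
            continue
        if name not in X.columns:
            raise KeyError(f"scenario stack missing predictor column {name!r}")
        eta += b * X[name].to_numpy()
    lam = np.exp(eta)  # intensity per m^2 x weight convention; per-cell below
    return (lam * stack.grid.cell_area).reshape(stack.grid.shape)


# ---------------------------------------------------------------------------
# evaluation


def elevation_test_labels(
    rng_range: ElevationalRange, elevation: np.ndarray
) -> np.ndarray:
    """Cell-level presence/absence from an expert elevational range."""
    return (elevation >= rng_range.low) & (elevation <= rng_range.high)


def evaluate_spatial_blocks(
    occ: OccurrenceTable,
    quad: QuadratureScheme,
    stack: LayerStack,
    bias: BiasCovariates | None,
    test_range: ElevationalRange,
    alpha: float = 0.5,
    lam: float = 0.0,
    lc_variant: str = "LC",
    n_blocks: int = 10,
    n_folds: int = 5,
) -> tuple[list[float], list[float | None]]:
    """Five-fold spatial-block evaluation.

    Ten contiguous rectangular blocks are paired into five folds. For each
    fold the model is refitted on the other folds, the left-out fold is
    predicted with bias covariates at 0, and TSS (at the fold's maxTSS
    threshold) plus the continuous Boyce index are scored against the
    elevational-range presence/absence labels. Folds with a single test
    class are excluded.
    """
    X, scaler, ref, levels = build_design(stack, bias, lc_variant)
    Xc = X.to_numpy()
    keep = Xc.std(axis=0) > 0
    colnames = [c for c, k in zip(X.columns, keep) if k]
    Xc = Xc[:, keep]
    z, w, rows = _ppm_rows(quad, Xc)
    cells = np.concatenate([quad.presence_cells, quad.quad_cells])
    fold_of_cell = blocks_to_folds(spatial_blocks(quad.grid, n_blocks), n_folds).ravel()
    fold = fold_of_cell[cells]

    X0, _, _, _ = build_design(
        stack, None if bias is None else bias.zeroed(), lc_variant,
        scaler=scaler, lc_reference=ref, lc_levels=levels,
    )
    X0c = X0[colnames].to_numpy()
    labels_all = elevation_test_labels(test_range, stack.layers["ELEV"]).ravel()

    tss_scores: list[float] = []
    boyce_scores: list[float | None] = []
    for f in range(n_folds):
        tr = fold != f
        if not tr.any() or tr.all():
            continue
        test_cells = np.nonzero(fold_of_cell == f)[0]
        lab = labels_all[test_cells]
        if lab.all() or not lab.any():
            continue  # undefined scores on single-class folds
        params = _fit_glm(z[tr], w[tr], rows[tr], lam, alpha)
        pred = np.exp(params[0] + X0c[test_cells] @ params[1:])
        q99 = np.quantile(pred, 0.99) or 1.0
        scaled = np.minimum(pred / q99, 1.0)
        thr, _ = max_tss_threshold(scaled, lab)
        tss_scores.append(tss(scaled, lab, thr))
        boyce_scores.append(boyce(scaled[lab], scaled))
    return tss_scores, boyce_scores


# ---------------------------------------------------------------------------
# projection


def _rescale(intensity: np.ndarray, q99: float) -> np.ndarray:
    return np.minimum(intensity / q99, 1.0) if q99 > 0 else np.zeros_like(intensity)


def project_ensemble(
    models: list[SpeciesModel],
    current_stack: LayerStack,
    scenario_stacks: dict[str, LayerStack],
    test_range: ElevationalRange | None = None,
) -> dict[str, ScenarioCube]:
    """Ensemble projection for one species.

    Intensities are predicted with bias covariates at 0, averaged across
    GCM/LC replicates (scenario keys "<horizon>-SSP<ssp>-gcm<g>") and
    across LC-classification variants, giving one map per (horizon, SSP)
    plus "current". Intensity is rescaled to (0, 1] by its 99th percentile
    over the current map and thresholded at the species' maxTSS threshold
    (mean over retained models) to produce binary and intensity-and-absence
    layers.
    """
    models = [m for m in models if m.retained]
    if not models:
        raise ValueError("no retained models to project")
    species = models[0].species

    per_model_current = [predict_intensity(m, current_stack) for m in models]
    current = np.mean(per_model_current, axis=0)
    q99 = float(np.quantile(current, 0.99))

    # species threshold: mean of per-model maxTSS thresholds on the current map
    if test_range is not None:
        thresholds = []
        labels = elevation_test_labels(test_range, current_stack.layers["ELEV"]).ravel()
        if labels.any() and not labels.all():
            for m, inten in zip(models, per_model_current):
                mq = float(np.quantile(inten, 0.99))
                thr, _ = max_tss_threshold(_rescale(inten.ravel(), mq), labels)
                m.threshold = thr
                thresholds.append(thr)
        threshold = float(np.mean(thresholds)) if thresholds else 0.5
    else:
        stored = [m.threshold for m in models if m.threshold is not None]
        threshold = float(np.mean(stored)) if stored else 0.5
    for m in models:
        m.rescale_q99 = q99

    groups: dict[str, list[str]] = {}
    for key in scenario_stacks:
        ens_key = "-".join(key.split("-")[:2]) if "-gcm" in key else key
        groups.setdefault(ens_key, []).append(key)

    out: dict[str, ScenarioCube] = {}

    def _cube(name: str, intensity: np.ndarray) -> ScenarioCube:
        binary = (_rescale(intensity, q99) >= threshold).astype(int)
        return ScenarioCube(species, name, intensity, binary)

    out["current"] = _cube("current", current)
    for ens_key, members in sorted(groups.items()):
        stacks = [scenario_stacks[k] for k in members]
        preds = [predict_intensity(m, s) for s in stacks for m in models]
        out[ens_key] = _cube(ens_key, np.mean(preds, axis=0))
    return out


def aggregate_to_coarse(cube: ScenarioCube, factor: int) -> ScenarioCube:
    """Block-mean the intensity-and-absence layer; coarse binary = any fine presence."""
    inten = block_aggregate(cube.intensity_and_absence, factor, "mean")
    binary = (block_aggregate(cube.binary.astype(float), factor, "mean") > 0).astype(int)
    return ScenarioCube(cube.species, cube.scenario, inten, binary, cube.mode, "coarse")
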