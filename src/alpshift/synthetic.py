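"""Synthetic montane study system with known ground truth.

Emulates the statistical structure the downstream analysis assumes: a
mountainous landscape with correlated-but-not-collinear climate and soil
predictors, species whose occurrence intensity is log-linear in those
predictors, geographically and environmentally biased presence-only
sampling, scenario-wise warming and land-cover transitions, a pure-birth
phylogeny with Brownian traits, per-species dispersal abilities and
independent expert-style elevational test ranges.

Every output is a pure function of (parameters, seed).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .grids import (
    BIAS_LAYERS,
    CLIMATE_LAYERS,
    SOIL_LAYERS,
    GridSpec,
    LayerStack,
    distance_to,
    smooth_field,
)

LC_CLASSES = ["grassland", "forest", "built_up", "cropland", "permanent_crops", "others"]
LC10_CLASSES = [
    "pasture",
    "semi_natural",
    "forest",
    "built_up",
    "permanent_crops",
    "irrigated_arable",
    "non_irrigated_arable",
    "abandoned",
    "others_low",
    "others_high",
]
TRAIT_NAMES = ["plant_height", "ldmc", "sla", "leaf_cn"]

# physical scalings for the standardized fields
_GDD_MEAN, _GDD_SD = 2000.0, 600.0
_BIO12_MEAN, _BIO12_SD = 1200.0, 300.0
_BIO4_MEAN, _BIO4_SD = 600.0, 120.0
_BIO15_MEAN, _BIO15_SD = 30.0, 8.0
GDD_PER_DEGREE = 180.0  # growing-degree-day gain per degree of warming


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated study system."""

    species: list[str]
    coef: pd.DataFrame  # species x (intercept + predictor) true log-linear coefficients
    expected_counts: pd.Series  # expected sampled points per species (after thinning)
    bias_params: dict
    scenario_params: dict
    seed: int


@dataclass
class OccurrenceTable:
    """Presence-only records; multiplicity > 1 only after bias-correction duplication."""

    records: pd.DataFrame  # columns: species, x, y, multiplicity
    provenance: str = "raw"

    def __post_init__(self) -> None:
        req = {"species", "x", "y", "multiplicity"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"occurrence table missing columns {sorted(missing)}")
        if len(self.records) and (self.records["multiplicity"] < 1).any():
            raise ValueError("multiplicity must be >= 1")

    def for_species(self, species: str) -> "OccurrenceTable":
        return OccurrenceTable(
            self.records[self.records["species"] == species].reset_index(drop=True),
            self.provenance,
        )

    @property
    def n_records(self) -> int:
        return len(self.records)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "raw") -> "OccurrenceTable":
        df = pd.read_csv(path)
        if "multiplicity" not in df.columns:
            df["multiplicity"] = 1
        return cls(df, provenance)


@dataclass(frozen=True)
class DispersalTraits:
    species: str
    d_min: float  # metres / year
    d_max: float  # metres / year
    ini_mat_age: int = 2  # years before a colonized cell produces propagules

    def __post_init__(self) -> None:
        if not (0 <= self.d_min <= self.d_max):
            raise ValueError("need 0 <= d_min <= d_max")
        if self.ini_mat_age < 0:
            raise ValueError("ini_mat_age must be >= 0")


@dataclass(frozen=True)
class ElevationalRange:
    """Expert-style 5th-95th percentile elevational range; evaluation only."""

    species: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("low must be <= high")


def _screen_correlations(stack: LayerStack) -> tuple[str, str, float] | None:
    names = list(CLIMATE_LAYERS + SOIL_LAYERS)
    mat = np.column_stack([stack.layers[n].ravel() for n in names])
    corr = np.corrcoef(mat, rowvar=False)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(corr[i, j]) >= 0.7:
                return names[i], names[j], float(corr[i, j])
    return None


def _draw_lines(shape: tuple[int, int], rng: np.random.Generator, n_lines: int) -> np.ndarray:
    """Binary raster of a few straight transects (a toy road network)."""
    out = np.zeros(shape, dtype=bool)
    nr, nc = shape
    for _ in range(n_lines):
        if rng.random() < 0.5:
            r0, r1 = rng.integers(0, nr, 2)
            cols = np.arange(nc)
            rows = np.clip(np.round(r0 + (r1 - r0) * cols / max(nc - 1, 1)).astype(int), 0, nr - 1)
            out[rows, cols] = True
        else:
            c0, c1 = rng.integers(0, nc, 2)
            rows = np.arange(nr)
            cols = np.clip(np.round(c0 + (c1 - c0) * rows / max(nr - 1, 1)).astype(int), 0, nc - 1)
            out[rows, cols] = True
    return out


def build_landscape(
    grid: GridSpec,
    seed: int,
    relief_amplitude: float = 3000.0,
    pa_fraction: float = 0.18,
    n_regions: int = 3,
    n_roads: int = 5,
    n_cities: int = 6,
    max_attempts: int = 25,
) -> LayerStack:
    """Generate a synthetic mountainous landscape.

    Elevation is a smooth random ridge/valley field scaled to
    ``[0, relief_amplitude]`` metres. Growing degree days decrease with
    elevation, annual precipitation increases, and the two seasonality
    layers plus both soil proxies are independent smooth fields; loadings
    are chosen so the pairwise Pearson correlation among the six continuous
    predictors stays below |r| = 0.7 (regenerated with perturbed noise
    otherwise). Also emits a 6-class land cover, a derived 10-class
    reclassification, a high-elevation-biased protected-area mask, a
    partition into contiguous regions ("countries"), and binary road/city
    layers used for the observer-bias field.
    """
    if relief_amplitude < 0:
        raise ValueError("relief_amplitude must be >= 0")
    base_rng = np.random.default_rng(seed)
    relief_raw = smooth_field(grid.shape, base_rng, sigma=max(grid.n_rows // 8, 2))
    if relief_amplitude > 0:
        lo, hi = relief_raw.min(), relief_raw.max()
        elev = (relief_raw - lo) / (hi - lo) * relief_amplitude
        elev_z = (elev - elev.mean()) / elev.std()
    else:
        elev = np.zeros(grid.shape)
        elev_z = np.zeros(grid.shape)

    last_offender = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7, attempt]))
        sig = max(grid.n_rows // 12, 2)
        n1, n2, n3, n4, n5, n6 = (smooth_field(grid.shape, rng, sig) for _ in range(6))
        gdd_z = -(np.sqrt(0.55) * elev_z + np.sqrt(0.45) * n1)
        bio12_z = np.sqrt(0.30) * elev_z + np.sqrt(0.70) * n2
        stack = LayerStack(
            grid,
            layers={
                "ELEV": elev,
                "GDD": np.clip(_GDD_MEAN + _GDD_SD * gdd_z, 0, None),
                "BIO12": np.clip(_BIO12_MEAN + _BIO12_SD * bio12_z, 0, None),
                "BIO4": np.clip(_BIO4_MEAN + _BIO4_SD * n3, 0, None),
                "BIO15": np.clip(_BIO15_MEAN + _BIO15_SD * n4, 0, None),
                "NITROGEN": np.clip(5.0 + 2.0 * n5, 1.0, 9.0),
                "CALCAREOUS": np.clip(50.0 + 25.0 * n6, 0.0, 100.0),
            },
        )
        offender = _screen_correlations(stack)
        if offender is None:
            break
        last_offender = offender
    else:
        a, b, r = last_offender
        raise RuntimeError(
            f"predictor correlation screen failed after {max_attempts} attempts: "
            f"|r({a},{b})| = {abs(r):.3f} >= 0.7"
        )

    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    # roads and cities, biased to the lowlands
    roads = _draw_lines(grid.shape, rng, n_roads)
    low_score = -elev_z + 0.5 * smooth_field(grid.shape, rng, 3)
    flat_order = np.argsort(low_score.ravel())[::-1]
    cities = np.zeros(grid.n_cells, dtype=bool)
    cities[flat_order[rng.choice(max(grid.n_cells // 20, n_cities), n_cities, replace=False)]] = True
    cities = cities.reshape(grid.shape)

    # 6-class land cover from elevation + noise, built-up pinned at cities
    lc_noise = smooth_field(grid.shape, rng, 3)
    score = elev_z + 0.8 * lc_noise
    lc = np.full(grid.shape, LC_CLASSES.index("others"))
    qs = np.quantile(score, [0.18, 0.42, 0.62, 0.78, 0.93])
    lc[score <= qs[0]] = LC_CLASSES.index("cropland")
    lc[(score > qs[0]) & (score <= qs[1])] = LC_CLASSES.index("permanent_crops")
    lc[(score > qs[1]) & (score <= qs[2])] = LC_CLASSES.index("forest")
    lc[(score > qs[2]) & (score <= qs[3])] = LC_CLASSES.index("grassland")
    lc[(score > qs[3]) & (score <= qs[4])] = LC_CLASSES.index("others")
    lc[score > qs[4]] = LC_CLASSES.index("others")
    near_city = distance_to(cities, grid.cell_size) <= grid.cell_size * 2
    lc[near_city] = LC_CLASSES.index("built_up")

    # protected areas biased toward high elevation, as contiguous-ish blobs
    pa_score = elev_z + 0.8 * smooth_field(grid.shape, rng, max(grid.n_rows // 10, 2))
    thresh = np.quantile(pa_score, 1 - pa_fraction)
    pa = pa_score > thresh

    # contiguous "countries": nearest of n_regions random centres
    X, Y = grid.cell_centres()
    cx = rng.uniform(grid.extent[0], grid.extent[2], n_regions)
    cy = rng.uniform(grid.extent[1], grid.extent[3], n_regions)
    d2 = (X[..., None] - cx) ** 2 + (Y[..., None] - cy) ** 2
    region = np.argmin(d2, axis=-1)

    stack.categorical_layers = {
        "LC": lc,
        "LC10": reclassify_lc10(lc, elev_z, stack.layers["BIO12"]),
        "PA": pa.astype(int),
        "REGION": region,
        "ROADS": roads.astype(int),
        "CITIES": cities.astype(int),
    }
    stack.categories = {"LC": list(LC_CLASSES), "LC10": list(LC10_CLASSES)}
    return stack


def reclassify_lc10(lc6: np.ndarray, elev_z: np.ndarray, bio12: np.ndarray) -> np.ndarray:
    """Fixed mapping of the 6-class land cover to a 10-class variant.

    Grassland splits into pasture (lower) / semi-natural (upper) on
    elevation; cropland splits into irrigated / non-irrigated on annual
    precipitation; 'others' splits on elevation.
    """
    out = np.empty_like(lc6)
    g = lc6 == LC_CLASSES.index("grassland")
    out[g & (elev_z <= 0)] = LC10_CLASSES.index("pasture")
    out[g & (elev_z > 0)] = LC10_CLASSES.index("semi_natural")
    out[lc6 == LC_CLASSES.index("forest")] = LC10_CLASSES.index("forest")
    out[lc6 == LC_CLASSES.index("built_up")] = LC10_CLASSES.index("built_up")
    out[lc6 == LC_CLASSES.index("permanent_crops")] = LC10_CLASSES.index("permanent_crops")
    c = lc6 == LC_CLASSES.index("cropland")
    med = np.median(bio12)
    out[c & (bio12 <= med)] = LC10_CLASSES.index("non_irrigated_arable")
    out[c & (bio12 > med)] = LC10_CLASSES.index("irrigated_arable")
    o = lc6 == LC_CLASSES.index("others")
    out[o & (elev_z <= 0)] = LC10_CLASSES.index("others_low")
    out[o & (elev_z > 0)] = LC10_CLASSES.index("others_high")
    return out


def make_scenarios(
    base: LayerStack,
    n_gcm: int,
    ssp_offsets: dict[tuple[int, int], float],
    lc_transition: np.ndarray,
    seed: int,
    gcm_noise_sd: float = 0.5,
) -> dict[str, LayerStack]:
    """Build one future stack per (horizon, SSP, GCM replicate).

    ``ssp_offsets`` maps (horizon, ssp) to a mean warming in degrees;
    warming raises growing degree days and lowers precipitation slightly,
    plus a GCM-specific smooth anomaly. Land cover is resampled cell-wise
    from ``lc_transition`` (rows must sum to 1; e.g. pasture -> forest
    models abandonment and succession). Soil is held constant.
    """
    lc_transition = np.asarray(lc_transition, dtype=float)
    k = len(LC_CLASSES)
    if lc_transition.shape != (k, k) or not np.allclose(lc_transition.sum(axis=1), 1.0):
        raise ValueError("lc_transition must be a row-stochastic 6x6 matrix")
    out: dict[str, LayerStack] = {}
    for (horizon, ssp), offset in sorted(ssp_offsets.items()):
        for g in range(n_gcm):
            rng = np.random.default_rng(np.random.SeedSequence([seed, horizon, ssp, g]))
            stack = base.copy()
            anomaly = gcm_noise_sd * smooth_field(base.grid.shape, rng, max(base.grid.n_rows // 10, 2))
            dT = offset + anomaly
            stack.layers["GDD"] = np.clip(stack.layers["GDD"] + GDD_PER_DEGREE * dT, 0, None)
            stack.layers["BIO12"] = np.clip(stack.layers["BIO12"] - 15.0 * dT, 0, None)
            stack.layers["BIO4"] = np.clip(stack.layers["BIO4"] + 8.0 * dT, 0, None)
            lc = stack.categorical_layers["LC"]
            u = rng.random(lc.shape)
            cum = np.cumsum(lc_transition, axis=1)
            new_lc = (u[..., None] > cum[lc]).sum(axis=-1)
            elev = stack.layers["ELEV"]
            elev_z = (elev - elev.mean()) / (elev.std() or 1.0)
            stack.categorical_layers["LC"] = new_lc
            stack.categorical_layers["LC10"] = reclassify_lc10(new_lc, elev_z, stack.layers["BIO12"])
            out[f"{horizon}-SSP{ssp}-gcm{g}"] = stack
    return out


def _brownian_traits(
    tree: dendropy.Tree, trait_names: list[str], rng: np.random.Generator, sigma: float = 1.0
) -> pd.DataFrame:
    """Independent Brownian motion per trait along the tree branches."""
    values: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = np.zeros(len(trait_names))
        else:
            el = node.edge.length or 0.0
            step = rng.normal(0.0, sigma * np.sqrt(max(el, 0.0)), len(trait_names))
            values[node] = values[node.parent_node] + step
    rows = {leaf.taxon.label: values[leaf] for leaf in tree.leaf_node_iter()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=trait_names)


def predictor_matrix(stack: LayerStack, standardize_by: LayerStack | None = None) -> pd.DataFrame:
    """Continuous predictors z-scored cell-wise (columns ordered climate then soil).

    When ``standardize_by`` is given, its means/sds are used — required so
    future scenarios are expressed on the current-period scale.
    """
    ref = standardize_by or stack
    cols = {}
    for name in CLIMATE_LAYERS + SOIL_LAYERS:
        ref_v = ref.layers[name]
        sd = ref_v.std() or 1.0
        cols[name] = ((stack.layers[name] - ref_v.mean()) / sd).ravel()
    return pd.DataFrame(cols)


def detection_bias_field(stack: LayerStack, params: dict) -> np.ndarray:
    """Thinning probability in (0, 1]: higher near roads/cities and in one region."""
    grid = stack.grid
    droad = np.sqrt(distance_to(stack.categorical_layers["ROADS"] > 0, grid.cell_size))
    dcity = np.sqrt(distance_to(stack.categorical_layers["CITIES"] > 0, grid.cell_size))
    country = (stack.categorical_layers["REGION"] == params["favoured_region"]).astype(float)
    log_b = (
        -params["w_road"] * droad / np.sqrt(grid.cell_size)
        - params["w_city"] * dcity / np.sqrt(grid.cell_size)
        + params["w_country"] * country
    )
    b = np.exp(log_b - log_b.max())
    return b


def simulate_species(
    base: LayerStack,
    n_species: int,
    seed: int,
    expected_points: float = 2000.0,
    bias_params: dict | None = None,
) -> tuple[
    SyntheticTruth,
    OccurrenceTable,
    dendropy.Tree,
    pd.DataFrame,
    list[DispersalTraits],
    list[ElevationalRange],
]:
    """Simulate species, biased occurrence samples, phylogeny, traits and test ranges.

    Half the species are cold-adapted (negative growing-degree-day
    coefficient, i.e. intensity peaking upslope), half thermophilic.
    Presence-only points are a Poisson draw from each species' intensity
    thinned by a shared detection-bias field. Dispersal abilities span two
    orders of magnitude. Expert elevational ranges are the 5th-95th
    percentiles of the noiseless intensity over the elevation gradient —
    derived from truth, never from the samples.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if bias_params is None:
        bias_params = {"w_road": 0.6, "w_city": 0.3, "w_country": 1.0, "favoured_region": 0}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    species = [f"sp{i:03d}" for i in range(n_species)]
    Z = predictor_matrix(base).to_numpy()
    pred_names = list(CLIMATE_LAYERS + SOIL_LAYERS)
    elev = base.layers["ELEV"].ravel()
    bias = detection_bias_field(base, bias_params).ravel()

    coefs = np.zeros((n_species, len(pred_names)))
    gdd_idx = pred_names.index("GDD")
    for s in range(n_species):
        beta = rng.normal(0.0, 0.45, len(pred_names))
        sign = -1.0 if s % 2 == 0 else 1.0  # even species are cold-adapted
        beta[gdd_idx] = sign * rng.uniform(0.6, 1.4)
        coefs[s] = beta

    eta = Z @ coefs.T  # cells x species
    # normalize so the expected sampled count (after bias thinning) is expected_points
    log_mu = eta + (np.log(expected_points) - logsumexp(eta + np.log(bias)[:, None], axis=0))
    mu = np.exp(log_mu)

    recs = []
    exp_counts = {}
    grid = base.grid
    nr, nc = grid.shape
    for s, name in enumerate(species):
        lam = mu[:, s] * bias
        exp_counts[name] = float(lam.sum())
        counts = rng.poisson(lam)
        idx = np.nonzero(counts)[0]
        for cell in idx:
            r, c = divmod(cell, nc)
            k = counts[cell]
            xs = grid.origin_x + (c + rng.random(k)) * grid.cell_size
            ys = grid.origin_y + (nr - r - rng.random(k)) * grid.cell_size
            for x, y in zip(xs, ys):
                recs.append((name, x, y))
    occ = OccurrenceTable(
        pd.DataFrame(recs, columns=["species", "x", "y"]).assign(multiplicity=1), "raw"
    )

    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=_RandomAdapter(rng),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = species[i]
    traits = _brownian_traits(tree, TRAIT_NAMES, rng).loc[species]

    log_dmax = rng.uniform(np.log10(10.0), np.log10(3000.0), n_species)
    dispersal = [
        DispersalTraits(species[s], d_min=10**log_dmax[s] / 10.0, d_max=10 ** log_dmax[s])
        for s in range(n_species)
    ]

    ranges = []
    for s, name in enumerate(species):
        lo, hi = _weighted_percentiles(elev, mu[:, s], (5.0, 95.0))
        ranges.append(ElevationalRange(name, lo, hi))

    truth = SyntheticTruth(
        species=species,
        coef=pd.DataFrame(coefs, index=species, columns=pred_names),
        expected_counts=pd.Series(exp_counts),
        bias_params=dict(bias_params),
        scenario_params={},
        seed=seed,
    )
    return truth, occ, tree, traits, dispersal, ranges


def _weighted_percentiles(values: np.ndarray, weights: np.ndarray, qs) -> np.ndarray:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    cdf = (cw - 0.5 * w) / cw[-1]
    return np.interp(np.asarray(qs) / 100.0, cdf, v)


class _RandomAdapter:
    """Expose the subset of random.Random that dendropy's simulator calls."""

    def __init__(self, rng: np.random.Generator) -> None:
        self._rng = rng

    def uniform(self, a: float, b: float) -> float:
        return float(self._rng.uniform(a, b))

    def random(self) -> float:
        return float(self._rng.random())

    def expovariate(self, rate: float) -> float:
        return float(self._rng.exponential(1.0 / rate))

    def sample(self, population, k):
        population = list(population)
        idx = self._rng.choice(len(population), size=k, replace=False)
        return [population[i] for i in idx]

    def choice(self, seq):
        return seq[int(self._rng.integers(len(seq)))]

    def shuffle(self, x):
        self._rng.shuffle(x)

    def randint(self, a, b):
        return int(self._rng.integers(a, b + 1))

    def gauss(self, mu, sigma):
        return float(self._rng.normal(mu, sigma))
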