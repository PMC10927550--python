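"""End-to-end orchestration with content-hash stage caching.

Stage order mirrors the analysis workflow: synthesize the study system,
build bias covariates, filter and bias-correct occurrences, fit and
evaluate the point-process models, project ensembles, apply dispersal
modes, aggregate to the coarse grid, compute diversity metrics, run the
prioritization and write the report. Each stage's result is cached under
the output directory keyed by a hash of its parameters and its upstream
stages' hashes, so a rerun with an unchanged config is a pure cache hit
and a parameter change reruns only the affected tail of the pipeline.
"""

from __future__ import annotations

import hashlib
import json
import pickle
import time
import warnings
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import bias as bias_mod
from . import dispersal as disp_mod
from . import diversity as div_mod
from . import ppm as ppm_mod
from . import prioritize as pri_mod
from . import range_change as rc_mod
from .config import PipelineConfig
from .grids import block_aggregate, write_ascii_grid
from .synthetic import (
    DispersalTraits,
    build_landscape,
    make_scenarios,
    simulate_species,
)
from .trees import FeatureTree

ELEV_STRATA_EDGES = [700.0, 1500.0, 2200.0, 3000.0]


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


class _StageCache:
    def __init__(self, root: Path) -> None:
        self.root = root
        root.mkdir(parents=True, exist_ok=True)

    def path(self, stage: str) -> Path:
        return self.root / f"{stage}.pkl"

    def load(self, stage: str, key: str):
        p = self.path(stage)
        kp = self.root / f"{stage}.hash"
        if p.exists() and kp.exists() and kp.read_text().strip() == key:
            with open(p, "rb") as fh:
                return pickle.load(fh)
        return None

    def store(self, stage: str, key: str, value) -> None:
        with open(self.path(stage), "wb") as fh:
            pickle.dump(value, fh)
        (self.root / f"{stage}.hash").write_text(key)


class _StopPipeline(Exception):
    """Carries the partial (manifest, results) out of an early-stopped run."""


def run_stages(cfg: PipelineConfig, stop_after: str, force: bool = False) -> dict:
    """Run the pipeline up to and including ``stop_after`` (cache-aware)."""
    try:
        return run_pipeline(cfg, force=force, stop_after=stop_after)
    except _StopPipeline as stop:
        manifest, results = stop.args
        return {"stages": manifest, "results": results}


def run_pipeline(cfg: PipelineConfig, force: bool = False, stop_after: str | None = None) -> dict:
    """Execute the full workflow; returns the manifest (with stage results attached).

    ``force`` ignores cached stage outputs; ``stop_after`` names the last
    stage to execute (used by the per-stage CLI subcommands).
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cache = _StageCache(out_dir / "cache")
    manifest: list[dict] = []
    results: dict = {}

    def stage(name: str, params: dict, upstream: list[str], fn):
        key = _hash({"params": params, "upstream": [results["_hash_" + u] for u in upstream]})
        t0 = time.time()
        value = None if force else cache.load(name, key)
        cached = value is not None
        if not cached:
            try:
                value = fn()
            except Exception as exc:  # annotate with the failing stage
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            cache.store(name, key, value)
        results[name] = value
        results["_hash_" + name] = key
        manifest.append(
            {"stage": name, "hash": key, "cached": cached, "wall_time_s": round(time.time() - t0, 3)}
        )
        if stop_after == name:
            raise _StopPipeline(manifest, results)
        return value

    grid = cfg.grid()

    # -- synthesize the study system ---------------------------------------
    def _simulate():
        base = build_landscape(
            grid, cfg.seed, cfg.relief_amplitude, pa_fraction=cfg.pa_fraction
        )
        truth, occ, tree, traits, dispersal, ranges = simulate_species(
            base, cfg.n_species, cfg.seed + 1, expected_points=cfg.expected_points
        )
        scenarios = make_scenarios(
            base, cfg.n_gcm, cfg.ssp_offsets(), np.array(cfg.lc_transition), cfg.seed + 2
        )
        return {
            "base": base,
            "truth": truth,
            "occ": occ,
            "tree_newick": tree.as_string(schema="newick"),
            "traits": traits,
            "dispersal": {d.species: d for d in dispersal},
            "ranges": {r.species: r for r in ranges},
            "scenarios": scenarios,
        }

    sim = stage(
        "simulate",
        {
            "grid": [cfg.n_rows, cfg.n_cols, cfg.cell_size, cfg.fine_to_coarse_factor],
            "seed": cfg.seed,
            "relief": cfg.relief_amplitude,
            "pa": cfg.pa_fraction,
            "n_species": cfg.n_species,
            "points": cfg.expected_points,
            "scen": [cfg.horizons, cfg.ssps, cfg.warming, cfg.n_gcm, cfg.lc_transition],
        },
        [],
        _simulate,
    )
    base = sim["base"]

    # -- bias covariates -----------------------------------------------------
    def _biascov():
        cov = bias_mod.build_bias_covariates(
            sim["occ"],
            base.categorical_layers["ROADS"],
            base.categorical_layers["CITIES"],
            grid,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bias_mod.check_bias_correlations(cov, base)
        return cov

    biascov = stage("biascov", {}, ["simulate"], _biascov)

    # -- filter + environmental bias correction ------------------------------
    def _ebc():
        filtered, retained = bias_mod.filter_prevalence_and_cap(
            sim["occ"], grid, cfg.min_pixels, cfg.occ_cap, cfg.seed + 3
        )
        clustering = bias_mod.cluster_environment(base, cfg.k_clusters, cfg.seed + 4)
        frames = []
        for sp in retained:
            corrected = bias_mod.ebc_resample(
                filtered.for_species(sp),
                clustering,
                grid,
                max_dup=cfg.ebc_max_dup,
                seed=cfg.seed + 5,
                target=cfg.ebc_target,
            )
            frames.append(corrected.records)
        occ_corr = type(filtered)(pd.concat(frames, ignore_index=True), "bias-corrected")
        return {"occ": occ_corr, "retained": retained, "clustering": clustering}

    ebc = stage(
        "ebc",
        {"min_pixels": cfg.min_pixels, "cap": cfg.occ_cap, "K": cfg.k_clusters,
         "max_dup": cfg.ebc_max_dup, "target": cfg.ebc_target},
        ["simulate"],
        _ebc,
    )

    # -- fit + evaluate ------------------------------------------------------
    def _fit():
        models: dict[str, list[ppm_mod.SpeciesModel]] = {}
        for sp in ebc["retained"]:
            occ_sp = ebc["occ"].for_species(sp)
            quad = ppm_mod.choose_quadrature(
                base, occ_sp, biascov, seed=cfg.seed + 6, n0=cfg.quad_n0, tol=cfg.quad_tol
            )
            fits = []
            for variant in cfg.lc_variants:
                m = ppm_mod.fit_ppm(
                    occ_sp, quad, base, biascov,
                    alpha=cfg.alpha, lam_grid=tuple(cfg.lam_grid),
                    lc_variant=variant, n_blocks=cfg.n_blocks, n_folds=cfg.n_folds,
                    seed=cfg.seed + 7, species=sp,
                )
                ts, bs = ppm_mod.evaluate_spatial_blocks(
                    occ_sp, quad, base, biascov, sim["ranges"][sp],
                    alpha=cfg.alpha, lam=m.lam, lc_variant=variant,
                    n_blocks=cfg.n_blocks, n_folds=cfg.n_folds,
                )
                m.fold_tss, m.fold_boyce = ts, bs
                m.retained = ppm_mod.apply_retention_rule(
                    m.mean_tss, m.mean_boyce, cfg.retention_cutoff
                )
                fits.append(m)
            models[sp] = fits
        return models

    models = stage(
        "fit",
        {"alpha": cfg.alpha, "lam_grid": cfg.lam_grid, "variants": cfg.lc_variants,
         "quad": [cfg.quad_n0, cfg.quad_tol], "blocks": [cfg.n_blocks, cfg.n_folds],
         "cutoff": cfg.retention_cutoff},
        ["simulate", "biascov", "ebc"],
        _fit,
    )

    # -- project -------------------------------------------------------------
    def _project():
        cubes: dict[str, dict[str, ppm_mod.ScenarioCube]] = {}
        for sp, fits in models.items():
            retained = [m for m in fits if m.retained]
            if not retained:
                continue
            cubes[sp] = ppm_mod.project_ensemble(
                retained, base, sim["scenarios"], test_range=sim["ranges"][sp]
            )
        if not cubes:
            raise RuntimeError("no species retained any model")
        return cubes

    cubes = stage("project", {}, ["fit"], _project)
    ens_keys = sorted({k for d in cubes.values() for k in d if k != "current"})

    # -- dispersal modes -----------------------------------------------------
    def _disperse():
        out: dict[str, dict[str, dict[str, ppm_mod.ScenarioCube]]] = {}
        for sp, sc in cubes.items():
            traits = sim["dispersal"].get(sp)
            out[sp] = {}
            for key in ens_keys:
                horizon = int(key.split("-")[0])
                out[sp][key] = disp_mod.assemble_modes(
                    sc["current"], sc[key], traits,
                    horizon_years=horizon - 2000, cell_size=grid.cell_size,
                    seed=cfg.seed + 8,
                )
        return out

    modes = stage("disperse", {"mode": cfg.dispersal_mode}, ["project"], _disperse)

    # -- aggregate to the coarse grid ---------------------------------------
    def _aggregate():
        f = cfg.fine_to_coarse_factor
        coarse: dict[str, dict[str, ppm_mod.ScenarioCube]] = {}
        for sp in cubes:
            coarse[sp] = {"current": ppm_mod.aggregate_to_coarse(cubes[sp]["current"], f)}
            for key in ens_keys:
                for mode_name, cube in modes[sp][key].items():
                    coarse[sp][f"{key}|{mode_name}"] = ppm_mod.aggregate_to_coarse(cube, f)
        return coarse

    coarse = stage("aggregate", {"factor": cfg.fine_to_coarse_factor}, ["disperse"], _aggregate)
    species_list = sorted(coarse)

    # -- diversity -----------------------------------------------------------
    def _diversity():
        phylo = FeatureTree.from_newick(sim["tree_newick"]).reindex(species_list)
        functional = FeatureTree.from_traits(sim["traits"].loc[species_list])

        def amatrix(scenario_key: str) -> np.ndarray:
            return np.column_stack(
                [coarse[sp][scenario_key].intensity_and_absence.ravel() for sp in species_list]
            )

        metrics = {"current": div_mod.cell_metrics(amatrix("current"), phylo, functional)}
        for key in ens_keys:
            metrics[key] = div_mod.cell_metrics(
                amatrix(f"{key}|{cfg.dispersal_mode}"), phylo, functional
            )
        weights = div_mod.uniqueness_weights(phylo, functional, amatrix("current"))
        return {"metrics": metrics, "weights": weights, "phylo": phylo, "functional": functional}

    diversity = stage("diversity", {"mode": cfg.dispersal_mode}, ["aggregate"], _diversity)

    # -- prioritization ------------------------------------------------------
    coarse_grid = grid.coarse()
    f = cfg.fine_to_coarse_factor
    pa_coarse = (
        block_aggregate(base.categorical_layers["PA"].astype(float), f, "mean") >= 0.5
    ).ravel()

    def _prioritize():
        weights = diversity["weights"].loc[species_list].to_numpy()
        ranks: dict[str, pri_mod.PriorityRank] = {}
        for scen in ["current"] + ens_keys:
            key = "current" if scen == "current" else f"{scen}|{cfg.dispersal_mode}"
            vals = np.column_stack(
                [coarse[sp][key].intensity_and_absence.ravel() for sp in species_list]
            )
            keep = vals.sum(axis=0) > 0
            F = pri_mod.FeatureMatrix(
                vals[:, keep],
                weights[keep],
                [s for s, k in zip(species_list, keep) if k],
            )
            if cfg.algorithm.lower() == "caz":
                ranks[scen] = pri_mod.rank_caz(F, pa_coarse, mode="expansion")
            else:
                ranks[scen] = pri_mod.rank_abf(F, z=cfg.abf_z, pa_mask=pa_coarse, mode="expansion")
            if scen == "current":
                extra: dict[str, np.ndarray] = {}
                vk = vals[:, keep]
                for tree in (diversity["phylo"], diversity["functional"]):
                    msub = tree.reindex([s for s, k in zip(species_list, keep) if k]).membership
                    branch_vals = np.stack(
                        [vk[:, row].max(axis=1) if row.any() else np.zeros(len(vk)) for row in msub],
                        axis=1,
                    )
                    extra[f"mean_{tree.kind}_branch"] = branch_vals.mean(axis=1)
                extra["range"] = (vk > 0).sum(axis=1).astype(float)
                pr_scores = div_mod.rarity(vk, diversity["phylo"].reindex(
                    [s for s, k in zip(species_list, keep) if k]))
                extra["phylo_rarity"] = np.nan_to_num(pr_scores) * vk.sum(axis=1)
                results["_curves"] = pri_mod.performance_curves(ranks[scen], F, extra_layers=extra)
        elev_coarse = block_aggregate(base.layers["ELEV"], f, "mean").ravel()
        stratum = np.digitize(elev_coarse, ELEV_STRATA_EDGES)
        region_fine = base.categorical_layers["REGION"]
        region_coarse = np.array(
            [
                np.bincount(block.ravel()).argmax()
                for block in region_fine.reshape(
                    coarse_grid.n_rows, f, coarse_grid.n_cols, f
                ).transpose(0, 2, 1, 3).reshape(-1, f, f)
            ]
        )
        counts, summary = pri_mod.expansion_overlap(
            ranks, pa_coarse, cfg.top_fraction, region=region_coarse, elevation_stratum=stratum
        )
        return {"ranks": ranks, "overlap_counts": counts, "summary": summary,
                "curves": results.pop("_curves")}

    prior = stage(
        "prioritize",
        {"alg": cfg.algorithm, "z": cfg.abf_z, "top": cfg.top_fraction, "mode": cfg.dispersal_mode},
        ["diversity"],
        _prioritize,
    )

    # -- report --------------------------------------------------------------
    def _report():
        elev = base.layers["ELEV"]
        changes_by_scen: dict[str, list[rc_mod.SpeciesChange]] = {}
        for key in ens_keys:
            changes = []
            for sp in species_list:
                p95 = rc_mod.elevation_p95(ebc["occ"].for_species(sp), elev, grid)
                changes.append(
                    rc_mod.species_change(
                        sp,
                        cubes[sp]["current"].binary,
                        modes[sp][key][cfg.dispersal_mode].binary,
                        p95,
                    )
                )
            changes_by_scen[key] = changes
        tables = {k: rc_mod.classify_and_tabulate(v) for k, v in changes_by_scen.items()}

        # directional sanity: do cold-adapted species shift upslope?
        truth = sim["truth"]
        elev_flat = elev.ravel()
        upslope = {}
        last = ens_keys[-1]
        for sp in species_list:
            cur = cubes[sp]["current"].intensity_and_absence.ravel()
            fut = cubes[sp][last].intensity_and_absence.ravel()
            if cur.sum() <= 0 or fut.sum() <= 0:
                continue
            upslope[sp] = float(
                np.average(elev_flat, weights=fut) - np.average(elev_flat, weights=cur)
            )
        cold = [sp for sp in upslope if truth.coef.loc[sp, "GDD"] < 0]
        frac_up = (
            float(np.mean([upslope[sp] > 0 for sp in cold])) if cold else np.nan
        )
        return {
            "changes": changes_by_scen,
            "tables": tables,
            "upslope_shift_m": upslope,
            "cold_adapted_upslope_fraction": frac_up,
            "protected_fraction_before": prior["summary"]["protected_fraction_before"],
            "protected_fraction_after": prior["summary"]["protected_fraction_after"],
        }

    report = stage("report", {"mode": cfg.dispersal_mode}, ["project", "disperse", "prioritize"], _report)

    _write_artifacts(cfg, out_dir, sim, biascov, models, diversity, prior, report, coarse_grid)
    manifest_out = {
        "config_seed": cfg.seed,
        "stages": manifest,
        "species": species_list,
        "scenarios": ens_keys,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest_out, fh, indent=2)
    manifest_out["results"] = results
    return manifest_out


def _write_artifacts(
    cfg, out_dir: Path, sim, biascov, models, diversity, prior, report, coarse_grid
) -> None:
    """Human-readable exports: rasters, CSV/JSON stores, report, config."""
    cfg.to_yaml(out_dir / "config.yaml")
    sim["occ"].to_csv(out_dir / "occurrences.csv")
    sim["traits"].to_csv(out_dir / "traits.csv")
    (out_dir / "phylogeny.nwk").write_text(sim["tree_newick"])
    base = sim["base"]
    rdir = out_dir / "rasters"
    rdir.mkdir(exist_ok=True)
    for name, vals in base.layers.items():
        write_ascii_grid(rdir / f"{name}.asc", base.grid, vals)
    for name, vals in {**base.categorical_layers, **biascov.as_dict()}.items():
        write_ascii_grid(rdir / f"{name}.asc", base.grid, np.asarray(vals, dtype=float))
    pd.DataFrame(
        [
            {"species": d.species, "d_min": d.d_min, "d_max": d.d_max, "ini_mat_age": d.ini_mat_age}
            for d in sim["dispersal"].values()
        ]
    ).to_csv(out_dir / "dispersal_traits.csv", index=False)
    truth = sim["truth"]
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(
            {
                "species": truth.species,
                "coef": truth.coef.round(6).to_dict(orient="index"),
                "expected_counts": truth.expected_counts.round(3).to_dict(),
                "bias_params": truth.bias_params,
                "seed": truth.seed,
            },
            fh,
            indent=2,
        )
    with open(out_dir / "models.json", "w") as fh:
        json.dump(
            {
                sp: [
                    {
                        "lc_variant": m.lc_variant,
                        "coef": m.coef.round(8).to_dict(),
                        "alpha": m.alpha,
                        "lambda": m.lam,
                        "threshold": m.threshold,
                        "fold_tss": m.fold_tss,
                        "fold_boyce": m.fold_boyce,
                        "retained": m.retained,
                    }
                    for m in fits
                ]
                for sp, fits in models.items()
            },
            fh,
            indent=2,
        )
    for scen, r in prior["ranks"].items():
        write_ascii_grid(
            out_dir / f"rank_{scen.replace('|','_')}.asc", coarse_grid,
            r.rank.reshape(coarse_grid.shape),
        )
    write_ascii_grid(
        out_dir / "expansion_overlap.asc", coarse_grid,
        prior["overlap_counts"].reshape(coarse_grid.shape).astype(float),
    )
    frames = []
    for scen, df in diversity["metrics"].items():
        tidy = df.reset_index().melt(id_vars="cell", var_name="metric", value_name="value")
        tidy.insert(0, "scenario", scen)
        frames.append(tidy)
    pd.concat(frames, ignore_index=True).to_csv(out_dir / "cell_metrics.csv", index=False)
    prior["curves"].to_csv(out_dir / "representation_curves.csv", index=False)

    def _clean(o):
        if isinstance(o, dict):
            return {str(k): _clean(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [_clean(v) for v in o]
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, rc_mod.SpeciesChange):
            return vars(o)
        return o

    with open(out_dir / "report.json", "w") as fh:
        json.dump(
            _clean(
                {
                    "tables": report["tables"],
                    "cold_adapted_upslope_fraction": report["cold_adapted_upslope_fraction"],
                    "upslope_shift_m": report["upslope_shift_m"],
                    "protected_fraction_before": report["protected_fraction_before"],
                    "protected_fraction_after": report["protected_fraction_after"],
                    "overlap_summary": prior["summary"],
                }
            ),
            fh,
            indent=2,
        )
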