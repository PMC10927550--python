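"""Per-species range change, winner/loser classification and summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import OccurrenceTable

# elevational vegetation belts on 95th-percentile elevation, metres
ELEVATION_CLASSES = [
    ("colline", -np.inf, 700.0),
    ("montane", 700.0, 1500.0),
    ("subalpine", 1500.0, 2200.0),
    ("alpine", 2200.0, 3000.0),
    ("nival", 3000.0, np.inf),
]
STABLE_BAND = 1.0  # |percent change| below this counts as stable


@dataclass
class SpeciesChange:
    species: str
    range_current: int
    range_future: int
    percent_change: float
    change_class: str  # winner | loser | stable
    elevation_p95: float | None = None
    elevation_class: str | None = None


def percent_range_change(current_count: int, future_count: int) -> float:
    """Signed percent range change: |future - current| / current x 100, negative for losses."""
    if current_count <= 0:
        raise ValueError("undefined for species with zero current range")
    magnitude = abs(future_count - current_count) / current_count * 100.0
    return -magnitude if future_count < current_count else magnitude


def classify_change(pct: float, stable_band: float = STABLE_BAND) -> str:
    if abs(pct) < stable_band:
        return "stable"
    return "loser" if pct < 0 else "winner"


def elevation_p95(occ: OccurrenceTable, elevation: np.ndarray, grid) -> float:
    """Multiplicity-weighted 95th percentile of elevation at record locations.

    Linear interpolation between order statistics (the type-7 convention
    for unit weights).
    """
    df = occ.records
    if not len(df):
        raise ValueError("no records")
    row, col = grid.xy_to_rowcol(df["x"].to_numpy(), df["y"].to_numpy())
    vals = elevation[row, col]
    w = df["multiplicity"].to_numpy().astype(float)
    ok = np.isfinite(vals)
    if not ok.any():
        raise ValueError("all records fall on nodata cells")
    vals, w = vals[ok], w[ok]
    # multiplicities are integral, so the expanded sample gives the exact type-7 value
    return float(np.percentile(np.repeat(vals, np.round(w).astype(int)), 95))


def elevation_class(p95: float) -> str:
    for name, lo, hi in ELEVATION_CLASSES:
        if lo <= p95 < hi:
            return name
    return ELEVATION_CLASSES[-1][0]


def species_change(
    species: str,
    current_binary: np.ndarray,
    future_binary: np.ndarray,
    p95: float | None = None,
    stable_band: float = STABLE_BAND,
) -> SpeciesChange:
    cur = int(np.asarray(current_binary).sum())
    fut = int(np.asarray(future_binary).sum())
    pct = percent_range_change(cur, fut)
    return SpeciesChange(
        species,
        cur,
        fut,
        pct,
        classify_change(pct, stable_band),
        p95,
        elevation_class(p95) if p95 is not None else None,
    )


def classify_and_tabulate(
    changes: list[SpeciesChange],
    bins: list[float] | None = None,
) -> dict:
    """Report table: share of species per percent-change bin and per elevation class.

    ``bins`` are strictly increasing edges partitioning the signed
    percent-change axis. Also returns headline winner/loser/stable shares.
    """
    if bins is None:
        bins = [-100.0, -75.0, -50.0, -25.0, 0.0, 25.0, 50.0, 75.0, 100.0, np.inf]
    edges = np.asarray(bins, dtype=float)
    if (np.diff(edges) <= 0).any():
        raise ValueError("bins must be strictly increasing (non-overlapping)")
    df = pd.DataFrame(
        {
            "species": [c.species for c in changes],
            "pct": [c.percent_change for c in changes],
            "cls": [c.change_class for c in changes],
            "elev_cls": [c.elevation_class for c in changes],
        }
    ).sort_values("species", kind="stable")
    n = len(df)
    shares = df["cls"].value_counts(normalize=True).to_dict()
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (df["pct"] >= lo) & (df["pct"] < hi)
        sub = df[sel]
        comp = (
            sub["elev_cls"].value_counts(normalize=True).to_dict() if len(sub) else {}
        )
        rows.append(
            {
                "bin_low": float(lo),
                "bin_high": float(hi),
                "species_share": len(sub) / n if n else 0.0,
                "elevation_composition": comp,
            }
        )
    return {
        "n_species": n,
        "winner_share": float(shares.get("winner", 0.0)),
        "loser_share": float(shares.get("loser", 0.0)),
        "stable_share": float(shares.get("stable", 0.0)),
        "bins": rows,
    }
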