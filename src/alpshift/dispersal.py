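"""Dispersal-constrained range projections.

Future suitability maps assume unlimited dispersal. Two companions bound
the truth: a no-dispersal projection (future range restricted to cells
already occupied) and a limited-dispersal cellular automaton in which
mature occupied cells colonize empty suitable cells each year with a
distance-decaying probability, and newly colonized cells must reach a
maturity age (``ini_mat_age``, default 2 years) before producing
propagules themselves.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import fftconvolve

from .ppm import ScenarioCube
from .synthetic import DispersalTraits

KERNEL_FLOOR = 0.01  # colonization probability at exactly d_max


def dispersal_kernel(d_min: float, d_max: float, cell_size: float) -> np.ndarray:
    """Per-offset colonization probability on a (2R+1)^2 neighbourhood.

    Probability is 1 up to ``d_min`` (centre-to-centre), decays
    exponentially from 1 at d_min to ``KERNEL_FLOOR`` at ``d_max``, and is
    0 beyond d_max.
    """
    if d_min < 0 or d_max < d_min:
        raise ValueError("need 0 <= d_min <= d_max")
    r = int(np.floor(d_max / cell_size))
    size = 2 * r + 1
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    d = np.hypot(dy, dx) * cell_size
    k = np.zeros((size, size))
    if d_max > d_min:
        rate = np.log(1.0 / KERNEL_FLOOR) / (d_max - d_min)
        k = np.exp(-rate * np.clip(d - d_min, 0.0, None))
    else:
        k = (d <= d_min).astype(float)
    k[d <= d_min] = 1.0
    k[d > d_max] = 0.0
    return k


def run_automaton(
    current_binary: np.ndarray,
    future_binary: np.ndarray,
    traits: DispersalTraits,
    n_years: int,
    cell_size: float,
    seed: int = 0,
) -> np.ndarray:
    """Yearly colonization automaton; returns the limited-dispersal binary map.

    Initial occupancy is the current range with standing populations
    already mature. Each year, in order: (1) occupied cells unsuitable
    under the future map are extirpated, (2) every mature occupied cell
    attempts to colonize each empty suitable cell within ``d_max``
    (independent per-source successes, at most one colonization per target
    per year), (3) ages increment. One uniform draw per (target, year) is
    consumed regardless of the kernel, so widening the kernel never
    flips a success into a failure under the same seed.
    """
    current_binary = np.asarray(current_binary).astype(bool)
    future_binary = np.asarray(future_binary).astype(bool)
    if current_binary.shape != future_binary.shape:
        raise ValueError("current and future grids do not conform")
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    maturity = max(traits.ini_mat_age, 1)
    age = np.where(current_binary, maturity, 0)

    kernel = dispersal_kernel(traits.d_min, traits.d_max, cell_size)
    centre = kernel.shape[0] // 2
    kernel[centre, centre] = 0.0  # a source cannot colonize itself
    log_miss = np.log1p(-np.minimum(kernel, 1.0 - 1e-12))
    for _ in range(n_years):
        age[~future_binary] = 0  # extirpation under the target-period habitat
        u = rng.random(age.shape)
        mature = (age >= maturity).astype(float)
        if kernel.size > 1 and mature.any():
            total_log_miss = fftconvolve(mature, log_miss, mode="same")
            p_col = 1.0 - np.exp(np.minimum(total_log_miss, 0.0))
            newly = (age == 0) & future_binary & (u < p_col)
        else:
            newly = np.zeros_like(age, dtype=bool)
        age[age > 0] += 1
        age[newly] = 1
    return (age > 0).astype(int)


def assemble_modes(
    cube_current: ScenarioCube,
    cube_future: ScenarioCube,
    traits: DispersalTraits | None,
    horizon_years: int,
    cell_size: float,
    seed: int = 0,
) -> dict[str, ScenarioCube]:
    """Unlimited-, no- and limited-dispersal variants of a future projection.

    unlimited = the future binary as-is; none = future ∩ current; limited
    = the automaton output. Each mode's intensity-and-absence layer is the
    future intensity masked by the mode's binary. Species without
    dispersal traits fall back to unlimited with a warning.
    """
    cur = cube_current.binary.astype(bool)
    fut = cube_future.binary.astype(bool)
    out = {}
    out["unlimited"] = ScenarioCube(
        cube_future.species, cube_future.scenario, cube_future.intensity, fut.astype(int),
        mode="unlimited", resolution=cube_future.resolution,
    )
    out["none"] = ScenarioCube(
        cube_future.species, cube_future.scenario, cube_future.intensity,
        (fut & cur).astype(int), mode="none", resolution=cube_future.resolution,
    )
    if traits is None:
        warnings.warn(
            f"species {cube_future.species!r} has no dispersal traits; "
            "limited mode falls back to unlimited"
        )
        limited = fut.astype(int)
    else:
        limited = run_automaton(cur, fut, traits, horizon_years, cell_size, seed)
    out["limited"] = ScenarioCube(
        cube_future.species, cube_future.scenario, cube_future.intensity, limited,
        mode="limited", resolution=cube_future.resolution,
    )
    return out
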