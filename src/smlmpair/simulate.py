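"""Synthetic two-channel cells with known ground truth, and parameter sweeps.

The simulator emulates the *output of grouping* — per-channel molecule sets
— inside a circular cell of configurable area (default 250 um^2).  A stated
fraction of the molecules are truly bound: the A member of each bound pair
is uniform in the circle and its B partner sits at exactly
``pair_distance`` in a uniformly random direction.  All remaining molecules
of both channels are independent and uniform (complete spatial
randomness).  Because these are molecules, not blinks, sweeps exercise
pairing + association directly; :func:`simulate_blinks` exists separately
to produce blink-level fixtures with ground-truth emitter labels for
testing the grouping stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .association import AssociationParams, analyze_cell

__all__ = [
    "SimulationSpec",
    "SimTruth",
    "circle_radius_nm",
    "simulate_cell",
    "run_sweep",
    "normalize_fraction",
    "simulate_blinks",
]


@dataclass(frozen=True)
class SimulationSpec:
    """One synthetic cell: molecule count per channel, geometry, binding."""

    n_per_channel: int
    fraction_bound: float = 0.0
    pair_distance: float = 10.0
    area_um2: float = 250.0

    def __post_init__(self) -> None:
        if self.n_per_channel < 1:
            raise ValueError("n_per_channel must be >= 1")
        if not 0.0 <= self.fraction_bound <= 1.0:
            raise ValueError("fraction_bound must be in [0, 1]")
        if self.pair_distance < 0:
            raise ValueError("pair_distance must be >= 0")
        if not self.area_um2 > 0:
            raise ValueError("area_um2 must be positive")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated cell."""

    bound_index_pairs: tuple[tuple[int, int], ...]  # (A id, B id)
    circle_radius: float  # nm


def circle_radius_nm(area_um2: float) -> float:
    """Radius in nm of a circle with the given area in um^2."""
    return math.sqrt(area_um2 * 1e6 / math.pi)


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    rad = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * (2.0 * math.pi)
    return np.column_stack((rad * np.cos(theta), rad * np.sin(theta)))


def _molecule_table(pos: np.ndarray, channel: str) -> pd.DataFrame:
    n = len(pos)
    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1, dtype=np.int64),
            "channel": channel,
            "x": pos[:, 0],
            "y": pos[:, 1],
            "n_locs": np.ones(n, dtype=np.int64),
            "accuracy": np.nan,
            "frame_first": np.ones(n, dtype=np.int64),
            "frame_last": np.ones(n, dtype=np.int64),
        }
    )


def simulate_cell(
    spec: SimulationSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw one synthetic cell.

    ``round(fraction_bound * n)`` bound pairs are placed first (ids 1..k in
    both channels, so truth pairs are (i, i)); the rest of each channel is
    uniform and independent.  B partners keep their exact separation and may
    overhang the circle edge by up to ``pair_distance`` — separation
    fidelity is preferred over strict containment.
    """
    n = spec.n_per_channel
    R = circle_radius_nm(spec.area_um2)
    k = int(round(spec.fraction_bound * n))

    pos_a = _uniform_disc(rng, n, R)
    theta = rng.random(k) * (2.0 * math.pi)
    offsets = spec.pair_distance * np.column_stack((np.cos(theta), np.sin(theta)))
    pos_b = np.empty_like(pos_a)
    pos_b[:k] = pos_a[:k] + offsets
    pos_b[k:] = _uniform_disc(rng, n - k, R)

    truth = SimTruth(
        bound_index_pairs=tuple((i + 1, i + 1) for i in range(k)),
        circle_radius=R,
    )
    return _molecule_table(pos_a, "A"), _molecule_table(pos_b, "B"), truth


def run_sweep(
    densities: list[int],
    fractions_bound: list[float],
    pair_distances: list[float],
    n_reps: int = 30,
    assoc_params: AssociationParams = AssociationParams(),
    master_seed: int = 0,
    area_um2: float = 250.0,
) -> pd.DataFrame:
    """Simulate and analyze every condition x replicate of a parameter grid.

    Seeds are derived deterministically from (master_seed, condition index,
    replicate), so the sweep is reproducible and any sub-grid of a larger
    run reproduces the same per-cell results.
    """
    conditions = [
        (n, fb, pd_)
        for n in densities
        for fb in fractions_bound
        for pd_ in pair_distances
    ]
    if not conditions:
        raise ValueError("empty parameter grid")
    rows = []
    for ci, (n, fb, dist) in enumerate(conditions):
        for rep in range(n_reps):
            ss = np.random.SeedSequence([int(master_seed), ci, rep])
            rng = np.random.default_rng(ss)
            cell_seed = int(ss.generate_state(1)[0] % (2**31))
            spec = SimulationSpec(
                n_per_channel=n, fraction_bound=fb, pair_distance=dist, area_um2=area_um2
            )
            A, B, _ = simulate_cell(spec, rng)
            res = analyze_cell(A, B, replace(assoc_params, seed=cell_seed))
            rows.append(
                {
                    "n_per_channel": n,
                    "fraction_bound": fb,
                    "pair_distance": dist,
                    "replicate": rep,
                    "n_pairs": res.n_pairs,
                    "fraction_associated": res.fraction_associated,
                    "median_distance": res.median_distance,
                }
            )
    return pd.DataFrame(rows)


def normalize_fraction(f: float, f0_mean: float, f100_mean: float) -> float:
    """Rescale a measured fraction associated by matched 0% / 100% anchors.

    Maps the mean fraction at 0% true binding to 0 and at 100% to 1.
    Values below the 0% anchor come out negative — interpretable only as
    "below background".
    """
    if f100_mean == f0_mean:
        raise ValueError("degenerate anchors: f100_mean == f0_mean")
    return (f - f0_mean) / (f100_mean - f0_mean)


def simulate_blinks(
    emitters: pd.DataFrame,
    rng: np.random.Generator,
    sigma: float = 10.0,
    mean_blinks: float = 5.0,
    n_frames: int = 11_000,
    burst_length: int = 100,
) -> pd.DataFrame:
    """Expand emitter positions into blink-level localizations.

    Each emitter fires ``Geometric(mean = mean_blinks)`` localizations,
    Gaussian-scattered (``sigma`` nm) around its position, on frames drawn
    uniformly from a ``burst_length``-frame window placed uniformly at
    random in the stack.  The ``emitter`` column retains ground truth;
    ``accuracy`` is set to ``sigma``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rows = []
    next_id = 1
    for em in emitters.itertuples(index=False):
        count = int(rng.geometric(1.0 / mean_blinks)) if mean_blinks > 1 else 1
        start = int(rng.integers(1, max(2, n_frames - burst_length)))
        xs = em.x + rng.normal(0.0, sigma, count)
        ys = em.y + rng.normal(0.0, sigma, count)
        frames = start + rng.integers(0, burst_length, count)
        for j in range(count):
            rows.append(
                {
                    "channel": em.channel,
                    "x": xs[j],
                    "y": ys[j],
                    "frame": int(frames[j]),
                    "accuracy": float(sigma),
                    "id": next_id,
                    "emitter": int(em.id),
                }
            )
            next_id += 1
    t = pd.DataFrame(
        rows, columns=["channel", "x", "y", "frame", "accuracy", "id", "emitter"]
    )
    t.attrs["n_frames_total"] = int(n_frames)
    t.attrs["source"] = "simulate_blinks"
    return t
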