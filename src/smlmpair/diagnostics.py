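"""Parameter-selection sweeps for the grouping temporal window.

The temporal window of the grouping stage is chosen semi-empirically: run
the grouping over a range of window sizes and take the smallest window that
already merges most of what a larger window would merge — the knee where
the curve of molecules-remaining flattens toward its plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import pandas as pd

from .grouping import GroupingParams, group_molecules

__all__ = ["temporal_window_sweep", "knee_pick"]


def temporal_window_sweep(
    locs: pd.DataFrame, windows: list[int], p: GroupingParams = GroupingParams()
) -> pd.DataFrame:
    """Fraction of molecules remaining after grouping vs temporal window.

    Counts are normalized to the molecule count at window size 1, so the
    window list must include 1.  All other grouping parameters are held
    fixed.
    """
    windows = sorted(set(int(w) for w in windows))
    if 1 not in windows:
        raise ValueError("window list must include 1 (normalization reference)")
    counts = {}
    for w in windows:
        molecules, _ = group_molecules(locs, replace(p, temporal_window=w))
        counts[w] = len(molecules)
    ref = counts[1]
    if ref == 0:
        raise ValueError("no molecules at window 1; empty input?")
    return pd.DataFrame(
        {
            "temporal_window": windows,
            "molecules_remaining_fraction": [counts[w] / ref for w in windows],
        }
    )


def knee_pick(sweep: pd.DataFrame, slope_tolerance: float = 1e-4) -> int:
    """Smallest window at which the sweep has flattened.

    Scans forward differences of ``molecules_remaining_fraction`` per frame
    and returns the first window whose outgoing slope magnitude falls below
    ``slope_tolerance`` (fraction per frame).  The knee of such curves is a
    visual judgement; this rule operationalizes it and the tolerance is
    deliberately exposed.  If the curve is still falling at the end of the
    sweep, the largest window is returned with a warning.
    """
    if len(sweep) < 3:
        raise ValueError("knee_pick needs at least 3 sweep rows")
    s = sweep.sort_values("temporal_window", ignore_index=True)
    w = s["temporal_window"].to_numpy(dtype=float)
    f = s["molecules_remaining_fraction"].to_numpy(dtype=float)
    for i in range(len(s) - 1):
        slope = (f[i + 1] - f[i]) / (w[i + 1] - w[i])
        if abs(slope) < slope_tolerance:
            return int(w[i])
    warnings.warn("sweep never flattens below the slope tolerance; returning largest window")
    return int(w[-1])
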