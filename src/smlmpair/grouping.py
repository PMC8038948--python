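"""Collapse autocorrelated blinks into "molecules".

A single labeled target in dSTORM rarely produces a single localization: a
target may carry several primary/secondary antibodies, each antibody several
fluorophores, and each fluorophore blinks repeatedly before bleaching.  The
downstream association analysis assumes molecule positions are independent,
so repeated blinks must first be merged.

The algorithm runs in two stages per channel:

1. **Spatio-temporal local-density-maxima grouping.**  Among unassigned
   localizations, repeatedly find the localization with the most neighbors
   within ``radius`` (default 34.2 nm, the physical extent of an antibody
   stack) and within ``temporal_window`` frames (default 500, capturing
   long on/off cycles), assign it and all unassigned localizations inside
   both thresholds of it to one group, and recurse on the rest.
2. **Group-level merge.**  The same density-maxima search is repeated over
   the stage-1 groups, with the spatial criterion relaxed to
   ``merge_radius`` (default 200 nm) between provisional group mean
   positions and the temporal criterion applied to the gap between group
   frame intervals.  Maxima are re-evaluated after each merge until no two
   groups remain merge-eligible.  This deliberately aggressive pass removes
   residual redundancy (e.g. a second fluorophore on the same antibody
   stack) at the cost of occasionally chaining genuinely distinct nearby
   targets; keeping the temporal window in force is what lets the window
   size control how strongly temporally separated blink clusters merge.

A molecule's position is the mean of its member localizations' positions and
its accuracy is ``mean(member accuracies) / sqrt(n_locs)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["GroupingParams", "group_stage1", "group_stage2", "group_molecules"]

MOLECULE_COLUMNS = [
    "id",
    "channel",
    "x",
    "y",
    "n_locs",
    "accuracy",
    "frame_first",
    "frame_last",
]


@dataclass(frozen=True)
class GroupingParams:
    """Thresholds of the two-stage grouping algorithm (all in nm / frames)."""

    radius: float = 34.2
    temporal_window: int = 500
    merge_radius: float = 200.0

    def __post_init__(self) -> None:
        if not (self.radius > 0 and self.temporal_window > 0 and self.merge_radius > 0):
            raise ValueError("all grouping parameters must be strictly positive")


def group_stage1(locs: pd.DataFrame, p: GroupingParams) -> list[np.ndarray]:
    """Partition one channel's localizations by spatio-temporal density maxima.

    Returns a list of arrays of localization ids, one per group.  The seed of
    each group had the maximal spatio-temporal neighbor count among
    still-unassigned localizations when it was chosen; ties are broken by
    lowest id, then earliest frame, which makes the output independent of
    input row order.
    """
    if len(locs) == 0:
        return []
    if locs["channel"].nunique() > 1:
        raise ValueError("group_stage1 expects a single-channel table")

    order = np.argsort(locs["id"].to_numpy(), kind="stable")
    ids = locs["id"].to_numpy()[order]
    pos = locs[["x", "y"]].to_numpy(dtype=float)[order]
    frames = locs["frame"].to_numpy(dtype=np.int64)[order]

    n = len(ids)
    unassigned = np.ones(n, dtype=bool)
    groups: list[np.ndarray] = []
    while unassigned.any():
        idx = np.flatnonzero(unassigned)
        tree = cKDTree(pos[idx])
        neigh = tree.query_ball_point(pos[idx], r=p.radius)
        best_k = -1
        best_key = None
        best_members: np.ndarray | None = None
        for k, nb in enumerate(neigh):
            nb = np.asarray(nb, dtype=np.intp)
            close_t = np.abs(frames[idx[nb]] - frames[idx[k]]) <= p.temporal_window
            members = nb[close_t]
            count = len(members) - 1  # exclude self
            key = (-count, ids[idx[k]], frames[idx[k]])
            if best_key is None or key < best_key:
                best_key = key
                best_k = k
                best_members = members
        assert best_members is not None
        groups.append(np.sort(ids[idx[best_members]]))
        unassigned[idx[best_members]] = False
    return groups


def group_stage2(
    groups: list[np.ndarray], locs: pd.DataFrame, p: GroupingParams
) -> list[np.ndarray]:
    """Merge stage-1 groups by the density-maxima search at group level.

    A pair of groups is merge-eligible when their provisional mean positions
    are within ``merge_radius`` and the gap between their frame intervals is
    at most ``temporal_window``.  The group with most eligible neighbors is
    merged with all of them; maxima are then re-evaluated on the updated
    positions/intervals, so chains of pairwise-eligible groups can collapse
    into one molecule even if the chain spans more than ``merge_radius``.
    Terminates when no two remaining groups are merge-eligible.
    """
    if not groups:
        return []
    by_id = locs.set_index("id")
    current = [np.asarray(g) for g in groups]
    while len(current) > 1:
        # deterministic ordering: by smallest member id
        current.sort(key=lambda g: int(g.min()))
        centers = np.array(
            [by_id.loc[g, ["x", "y"]].to_numpy(dtype=float).mean(axis=0) for g in current]
        )
        first = np.array([by_id.loc[g, "frame"].min() for g in current])
        last = np.array([by_id.loc[g, "frame"].max() for g in current])
        tree = cKDTree(centers)
        neigh = tree.query_ball_point(centers, r=p.merge_radius)
        eligible = []
        for i, nb in enumerate(neigh):
            nb = np.asarray(nb, dtype=np.intp)
            gap = np.maximum(first[nb], first[i]) - np.minimum(last[nb], last[i])
            eligible.append(nb[gap <= p.temporal_window])
        counts = np.array([len(nb) - 1 for nb in eligible])
        if counts.max() == 0:
            break
        seed = int(np.argmax(counts))  # first max == lowest min-member-id
        members = sorted(int(m) for m in eligible[seed])
        merged = np.sort(np.concatenate([current[m] for m in members]))
        current = [g for m, g in enumerate(current) if m not in set(members)]
        current.append(merged)
    return current


def _molecule_row(member_ids: np.ndarray, by_id: pd.DataFrame) -> dict:
    sub = by_id.loc[member_ids]
    acc = sub["accuracy"].to_numpy(dtype=float)
    n = len(sub)
    accuracy = float(np.mean(acc) / np.sqrt(n)) if np.isfinite(acc).all() else np.nan
    return {
        "channel": sub["channel"].iloc[0],
        "x": float(sub["x"].mean()),
        "y": float(sub["y"].mean()),
        "n_locs": int(n),
        "accuracy": accuracy,
        "frame_first": int(sub["frame"].min()),
        "frame_last": int(sub["frame"].max()),
        "member_ids": np.asarray(member_ids, dtype=np.int64),
    }


def group_molecules(
    locs: pd.DataFrame, p: GroupingParams = GroupingParams()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run both grouping stages independently per channel.

    Returns
    -------
    molecules : pandas.DataFrame
        One row per molecule with columns
        ``id, channel, x, y, n_locs, accuracy, frame_first, frame_last``
        plus a ``member_ids`` column holding the underlying localization ids.
    assignments : pandas.DataFrame
        Columns ``id`` (localization) and ``molecule_id``; a disjoint cover
        of the input ids.
    """
    if len(locs) and locs["id"].duplicated().any():
        raise ValueError("localization ids must be unique")
    by_id = locs.set_index("id", drop=False) if len(locs) else locs
    rows = []
    for channel in sorted(locs["channel"].unique()) if len(locs) else []:
        sub = locs[locs["channel"] == channel]
        stage1 = group_stage1(sub, p)
        stage2 = group_stage2(stage1, sub, p)
        stage2.sort(key=lambda g: int(g.min()))
        for g in stage2:
            rows.append(_molecule_row(g, by_id))
    molecules = pd.DataFrame(
        rows, columns=MOLECULE_COLUMNS[1:] + ["member_ids"]
    ) if rows else pd.DataFrame(columns=MOLECULE_COLUMNS[1:] + ["member_ids"])
    molecules.insert(0, "id", np.arange(1, len(molecules) + 1, dtype=np.int64))

    assign_rows = []
    for _, row in molecules.iterrows():
        for lid in row["member_ids"]:
            assign_rows.append((int(lid), int(row["id"])))
    assignments = pd.DataFrame(assign_rows, columns=["id", "molecule_id"]).sort_values(
        "id", ignore_index=True
    ) if assign_rows else pd.DataFrame(columns=["id", "molecule_id"])
    return molecules, assignments
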