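"""Significance testing: Winsorization, replicate-blocked ANOVA, generalized omega^2.

Per-cell statistics (fraction associated, median pair distance) are
correlated within an experimental replicate, so replicates are treated as
the blocking / subject factor: cells are first averaged to one value per
replicate x condition, and each within-replicate treatment factor is tested
against its treatment x replicate interaction mean square (the classical
balanced within-subjects decomposition).  An optional between-subjects
factor (different cell samples per group, e.g. which RNA probe was imaged)
is tested against the replicate-within-group stratum.

Effect sizes are *generalized* omega^2 estimates, built from expected-mean-
square variance components so that values are comparable across designs
with and without repeated measures.  Conventional anchors: small ~0.01,
medium ~0.06, large ~0.14; null effects can legitimately come out slightly
negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "windsorize",
    "AnovaResult",
    "rm_anova",
    "generalized_omega_squared",
    "aggregate_cells_to_replicates",
]


def windsorize(sample: np.ndarray, z_threshold: float = 2.25) -> np.ndarray:
    """Pull in at most one extreme value per sample.

    If the single most extreme point has a z-score (computed from the full
    sample, ddof=1) at or above ``z_threshold``, it is replaced by the most
    extreme remaining value on the same side of the mean.  Identical
    samples (sd = 0) are returned unchanged; never alters more than one
    element and never widens the range.
    """
    values = np.asarray(sample, dtype=float).copy()
    if values.size < 3:
        raise ValueError("windsorize requires at least 3 values")
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        return values
    dev = np.abs(values - mean)
    i = int(np.argmax(dev))
    if dev[i] / sd < z_threshold:
        return values
    others = np.delete(values, i)
    values[i] = others.max() if values[i] > mean else others.min()
    return values


@dataclass
class AnovaResult:
    """Decomposition table plus the design info needed for effect sizes.

    ``table`` columns: term, kind ("fixed" or "random"), SS, df, MS, denom
    (name of the error stratum used for F), F, p, omega2_g (fixed terms
    only).
    """

    table: pd.DataFrame
    n_obs: int
    n_subjects: int
    n_groups: int
    within_levels: dict[str, int] = field(default_factory=dict)


def _T(df: pd.DataFrame, cols: tuple[str, ...], value: str) -> float:
    """Sum over cells of (cell total)^2 / (cell size) for a factor crossing."""
    if not cols:
        return float(df[value].sum() ** 2 / len(df))
    g = df.groupby(list(cols), observed=True)[value].agg(["sum", "size"])
    return float((g["sum"] ** 2 / g["size"]).sum())


def _ss_crossed(df: pd.DataFrame, factors: tuple[str, ...], value: str) -> float:
    """Inclusion-exclusion SS for a fully crossed term."""
    ss = 0.0
    for r in range(len(factors) + 1):
        for sub in combinations(factors, r):
            ss += (-1) ** (len(factors) - r) * _T(df, sub, value)
    return ss


def rm_anova(
    t: pd.DataFrame,
    value: str,
    within: list[str],
    replicate: str = "replicate",
    between: str | None = None,
) -> AnovaResult:
    """Balanced ANOVA with the replicate as a repeated measure.

    Parameters
    ----------
    t
        One row per replicate x condition (aggregate cell-level data first
        with :func:`aggregate_cells_to_replicates`).
    value
        Column holding the response.
    within
        One or two treatment factors varied within each replicate.
    replicate
        Blocking / subject column.
    between
        Optional factor distinguishing groups of replicates (subjects are
        nested in its levels).

    Raises on unbalanced tables (no imputation) and on designs with fewer
    than two replicates.
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("rm_anova supports 1 or 2 within factors")
    df = t.copy()
    group_cols = [between] if between else []
    # subjects are replicate labels, nested in the between groups when present
    df["_subj"] = (
        df[replicate].astype(str)
        if not between
        else df[between].astype(str) + "/" + df[replicate].astype(str)
    )

    cells = df.groupby(["_subj"] + within, observed=True).size()
    if (cells != 1).any():
        raise ValueError(
            "unbalanced design: every replicate must contribute exactly one "
            "value per condition (aggregate cells to replicate means first)"
        )
    n_cells_expected = int(np.prod([df[w].nunique() for w in within]))
    per_subj = df.groupby("_subj", observed=True).size()
    if (per_subj != n_cells_expected).any():
        raise ValueError("unbalanced design: missing condition cells for some replicates")

    N = len(df)
    subjects = df["_subj"].unique()
    s = len(subjects)
    b = df[between].nunique() if between else 1
    if s // b < 2:
        raise ValueError("at least 2 replicates per group are required")
    if between and s % b != 0:
        raise ValueError("unbalanced design: unequal replicates per between group")

    within_levels = {w: int(df[w].nunique()) for w in within}
    T0 = _T(df, (), value)
    ss_total = float((df[value] ** 2).sum()) - T0

    terms: list[dict] = []

    def add(term, kind, SS, dfree, denom=None):
        terms.append(
            {"term": term, "kind": kind, "SS": SS, "df": int(dfree), "denom": denom}
        )

    if between:
        add(between, "fixed", _ss_crossed(df, (between,), value), b - 1, "replicate")
    ss_subj = _T(df, ("_subj",), value) - (_T(df, (between,), value) if between else T0)
    add("replicate", "random", ss_subj, s - b)

    within_subsets = [c for r in (1, 2) for c in combinations(within, r) if r <= len(within)]
    for wset in within_subsets:
        dfw = int(np.prod([within_levels[w] - 1 for w in wset]))
        name = ":".join(wset)
        err_name = f"{name} x replicate"
        add(name, "fixed", _ss_crossed(df, wset, value), dfw, err_name)
        if between:
            add(
                f"{name}:{between}",
                "fixed",
                _ss_crossed(df, wset + (between,), value),
                dfw * (b - 1),
                err_name,
            )
        # error stratum: wset x subject(group)
        ss_err = 0.0
        for r in range(len(wset) + 1):
            for sub in combinations(wset, r):
                sign = (-1) ** (len(wset) - r)
                ss_err += sign * (
                    _T(df, sub + ("_subj",), value)
                    - (_T(df, sub + (between,), value) if between else _T(df, sub, value))
                )
        add(err_name, "random", ss_err, dfw * (s - b))

    table = pd.DataFrame(terms)
    table["SS"] = table["SS"].clip(lower=0.0)  # guard tiny negative round-off
    table["MS"] = table["SS"] / table["df"]

    # sanity: the decomposition must be complete
    assert abs(table["SS"].sum() - ss_total) <= 1e-8 * max(1.0, abs(ss_total))
    assert table["df"].sum() == N - 1

    ms = table.set_index("term")["MS"]
    F = np.full(len(table), np.nan)
    p = np.full(len(table), np.nan)
    for i, row in table.iterrows():
        if row["kind"] != "fixed":
            continue
        ms_den = ms[row["denom"]]
        df_den = int(table.loc[table["term"] == row["denom"], "df"].iloc[0])
        if ms_den == 0:
            warnings.warn(
                f"zero error mean square for term {row['term']!r}; F reported as inf"
            )
            F[i] = np.inf if row["MS"] > 0 else 0.0
            p[i] = 0.0 if row["MS"] > 0 else 1.0
        else:
            F[i] = row["MS"] / ms_den
            p[i] = sps.f.sf(F[i], row["df"], df_den)
    table["F"] = F
    table["p"] = p

    result = AnovaResult(
        table=table,
        n_obs=N,
        n_subjects=s,
        n_groups=b,
        within_levels=within_levels,
    )
    result.table["omega2_g"] = generalized_omega_squared(result)
    return result


def generalized_omega_squared(a: AnovaResult) -> pd.Series:
    """Generalized omega^2 per fixed term, from EMS variance components.

    For a fixed effect tested against error mean square ``MS_d``:

        sigma2_effect = df_effect * (MS_effect - MS_d) / N

    The denominator adds every variance component involving the replicate
    (the measured factor): the replicate stratum, each treatment x
    replicate stratum, and the residual mean square.  Components are not
    truncated at zero, so null effects produce slightly negative values.
    """
    table = a.table.set_index("term")
    within = list(a.within_levels)
    resid_name = f"{':'.join(within)} x replicate"
    ms_resid = float(table.loc[resid_name, "MS"])
    n_within_prod = int(np.prod(list(a.within_levels.values())))

    # random variance components (restricted-model EMS, one obs per cell)
    sigma_rand = ms_resid
    sigma_rand += (float(table.loc["replicate", "MS"]) - ms_resid) / n_within_prod
    for r in range(1, len(within)):
        for wset in combinations(within, r):
            name = f"{':'.join(wset)} x replicate"
            excluded = int(
                np.prod([a.within_levels[w] for w in within if w not in wset])
            )
            sigma_rand += (float(table.loc[name, "MS"]) - ms_resid) / excluded

    out = pd.Series(np.nan, index=a.table.index, dtype=float)
    for i, row in a.table.iterrows():
        if row["kind"] != "fixed":
            continue
        ms_d = float(table.loc[row["denom"], "MS"])
        sigma_eff = row["df"] * (row["MS"] - ms_d) / a.n_obs
        out[i] = sigma_eff / (sigma_eff + sigma_rand)
    return out


def aggregate_cells_to_replicates(
    cells: pd.DataFrame,
    value: str,
    replicate: str = "replicate",
    factors: list[str] | None = None,
) -> pd.DataFrame:
    """Mean of the per-cell statistic per replicate x condition.

    Raises if any condition is missing from a replicate — the downstream
    ANOVA requires a balanced design and silently dropping replicates would
    hide that.
    """
    factors = list(factors or [])
    out = (
        cells.groupby([replicate] + factors, observed=True, as_index=False)[value]
        .mean()
    )
    if factors:
        counts = out.groupby(replicate, observed=True).size()
        if counts.nunique() > 1:
            raise ValueError("unbalanced: some replicates are missing conditions")
    return out
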