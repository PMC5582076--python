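"""Selection-consistency analysis via rank indices and ranking distances.

For each year, every model under comparison ranks the lines by GEBV (lowest
GEBV = rank 1, highest = rank n; ties get average ranks) and the per-line
mean of those rank indices represents the line's standing in that year.
Sorting the population by the year-1 mean index from highest to lowest, the
ranking distance d of a line is the absolute difference between its two
years' mean indices, and the cumulative average

    dbar_n = (d_1 + ... + d_n) / n,  n = 1..N

traces how consistently the top of the ranking is preserved across years:
a flat, low profile at small n means elite lines keep their standing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["rank_by_gebv", "mean_rank_index", "ranking_distance_profile"]


def rank_by_gebv(gebv: pd.Series) -> pd.Series:
    """Ascending ranks 1..n of a GEBV vector; ties receive average ranks."""
    g = gebv.astype(float)
    if not np.isfinite(g.to_numpy()).all():
        raise ValueError("GEBVs must be finite to rank")
    return g.rank(method="average")


def mean_rank_index(rankings: list[pd.Series]) -> pd.Series:
    """Per-line arithmetic mean of rank indices across models.

    All rankings must cover exactly the same line set.
    """
    if not rankings:
        raise ValueError("at least one ranking required")
    base = set(rankings[0].index)
    for r in rankings[1:]:
        if set(r.index) != base:
            raise ValueError("rankings cover different line sets")
    aligned = pd.concat([r.reindex(rankings[0].index) for r in rankings], axis=1)
    return aligned.mean(axis=1).rename("mean_rank")


def ranking_distance_profile(
    mean_rank_year1: pd.Series, mean_rank_year2: pd.Series
) -> pd.DataFrame:
    """Ranking distances and cumulative averages, sorted by year-1 standing.

    Lines are ordered by the year-1 mean index descending (highest-GEBV
    first; ties broken by line id for determinism); d is the absolute
    difference between the two years' mean indices and dbar the running mean
    of d over the first n lines.  Returns a frame with columns
    (n, line, mean_rank_y1, mean_rank_y2, d, dbar).
    """
    if set(mean_rank_year1.index) != set(mean_rank_year2.index):
        raise ValueError("the two years cover different line sets")
    df = pd.DataFrame(
        {
            "line": mean_rank_year1.index,
            "mean_rank_y1": mean_rank_year1.to_numpy(dtype=float),
            "mean_rank_y2": mean_rank_year2.reindex(mean_rank_year1.index).to_numpy(
                dtype=float
            ),
        }
    )
    df = df.sort_values(
        ["mean_rank_y1", "line"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df["d"] = (df["mean_rank_y1"] - df["mean_rank_y2"]).abs()
    df["dbar"] = df["d"].expanding().mean()
    df.insert(0, "n", np.arange(1, len(df) + 1))
    return df
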