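"""Frequency-weighted metabolic pathway scoring.

Each species carries pathway presence scores in [0, 1] (a MACADAM-style
export with a two-level hierarchy: H1 category such as biosynthesis /
degradation / energy, H2 subcategory). The per-sample score of a pathway
is the abundance-weighted sum

    PS(sample, pathway) = sum_species freq(sample, species) * score(species, pathway)

which is linear in the frequencies; hierarchy rollups sum member pathway
scores and therefore conserve totals. Species absent from the database
contribute zero (logged with the covered frequency mass).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import DegenerateDataError, paired_t_one_sided

logger = logging.getLogger(__name__)


@dataclass
class PathwayDB:
    """Species x pathway scores plus the pathway hierarchy.

    scores: DataFrame species_id x pathway_id, values in [0, 1].
    hierarchy: DataFrame indexed by pathway_id with columns h1, h2.
    """

    scores: pd.DataFrame
    hierarchy: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.scores.to_numpy(dtype=float)
        if ((v < 0) | (v > 1)).any():
            raise ValueError("pathway scores must lie in [0, 1]")
        missing = self.scores.columns.difference(self.hierarchy.index)
        if len(missing):
            raise ValueError(f"pathways without hierarchy labels: {list(missing)[:3]}")

    def to_long(self) -> pd.DataFrame:
        long = self.scores.stack().rename("score").reset_index()
        long.columns = ["species_id", "pathway_id", "score"]
        return long.merge(
            self.hierarchy, left_on="pathway_id", right_index=True
        )


@dataclass
class PathwayScoreTable:
    """Per-sample aggregated pathway scores.

    scores: DataFrame samples x pathways; coverage: per-sample fraction of
    frequency mass belonging to species present in the database.
    """

    scores: pd.DataFrame
    coverage: pd.Series
    db: PathwayDB


def sample_pathway_scores(
    frequencies: pd.DataFrame, db: PathwayDB
) -> PathwayScoreTable:
    """Abundance-weighted pathway scores per sample.

    Species missing from the database contribute 0; the per-sample covered
    frequency fraction is reported and logged when below 1.
    """
    common = frequencies.columns.intersection(db.scores.index)
    coverage = frequencies[common].sum(axis=1)
    if len(common) < frequencies.shape[1]:
        logger.info(
            "pathway db covers %d/%d species (min sample coverage %.3f)",
            len(common), frequencies.shape[1], coverage.min() if len(common) else 0.0,
        )
    if len(common) == 0:
        scores = pd.DataFrame(
            0.0, index=frequencies.index, columns=db.scores.columns
        )
    else:
        scores = frequencies[common].to_numpy() @ db.scores.loc[common].to_numpy()
        scores = pd.DataFrame(
            scores, index=frequencies.index, columns=db.scores.columns
        )
    return PathwayScoreTable(scores=scores, coverage=coverage, db=db)


def rollup_hierarchy(table: PathwayScoreTable, level: str = "h1") -> pd.DataFrame:
    """Sum pathway scores within each H1/H2 category (conserves totals)."""
    if level not in ("h1", "h2"):
        raise ValueError("level must be 'h1' or 'h2'")
    labels = table.db.hierarchy[level].reindex(table.scores.columns)
    return table.scores.T.groupby(labels).sum().T


def group_shift_summary(
    table: PathwayScoreTable,
    meta: pd.DataFrame,
    level: str = "h1",
    tp_before: str = "T0",
    tp_after: str = "T3",
    direction: str = "increase",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per category and group: mean scores before/after fasting and a
    one-sided paired t-test on donor-matched category scores.

    Tests are run separately per group (RA / MetS); categories whose test
    is degenerate (e.g. identical values) report p = 1.
    """
    rolled = rollup_hierarchy(table, level=level)
    rows = []
    for group in sorted(meta["group"].unique()):
        sub = meta[meta["group"] == group]
        for cat in rolled.columns:
            piv = (
                pd.DataFrame(
                    {
                        "value": rolled.loc[sub.index, cat],
                        "donor": sub["donor"],
                        "timepoint": sub["timepoint"],
                    }
                )
                .pivot_table(index="donor", columns="timepoint", values="value")
            )
            if tp_before not in piv.columns or tp_after not in piv.columns:
                continue
            piv = piv[[tp_before, tp_after]].dropna()
            try:
                res = paired_t_one_sided(
                    piv[tp_before], piv[tp_after], direction=direction
                )
                p = res.p
            except DegenerateDataError:
                p = 1.0
            rows.append(
                {
                    "group": group,
                    "category": cat,
                    f"mean_{tp_before}": float(piv[tp_before].mean()),
                    f"mean_{tp_after}": float(piv[tp_after].mean()),
                    "p": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def species_change_profile(
    frequencies: pd.DataFrame,
    meta: pd.DataFrame,
    db: PathwayDB,
    h1: str = "biosynthesis",
    group: str = "RA",
    tp_before: str = "T0",
    tp_after: str = "T3",
    min_abs_change: float = 0.0,
) -> pd.DataFrame:
    """Per-species mean abundance change across fasting vs summed category
    score.

    delta_freq = mean frequency at tp_after - mean at tp_before over the
    group's donors; summed_score = the species' total score over the H1
    category's pathways. Output keeps species with |delta| > min_abs_change
    and is sorted by ascending delta (ties broken by species_id).
    """
    sub = meta[meta["group"] == group]
    before = frequencies.loc[sub.index[sub["timepoint"] == tp_before]]
    after = frequencies.loc[sub.index[sub["timepoint"] == tp_after]]
    delta = after.mean(axis=0) - before.mean(axis=0)
    pwys = db.hierarchy.index[db.hierarchy["h1"] == h1]
    summed = db.scores[pwys.intersection(db.scores.columns)].sum(axis=1)
    out = pd.DataFrame(
        {
            "delta_freq": delta,
            "summed_score": summed.reindex(delta.index).fillna(0.0),
        }
    )
    out.index.name = "species_id"
    out = out[np.abs(out["delta_freq"]) > min_abs_change]
    # stable sort after index sort: delta ties break toward smaller species_id
    return out.sort_index().sort_values("delta_freq", kind="stable")
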