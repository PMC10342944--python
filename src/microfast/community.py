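"""Community-level metrics: Simpson diversity, richness, taxonomy rollups,
group-specific species filters, the BMI correlation screen and per-donor
eukaryote frequency sums."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import welch_test, DegenerateDataError


@dataclass
class GroupedFrequencyPanel:
    """Species frequency table joined to cohort metadata.

    frequencies: DataFrame samples x species (rows sum to 1).
    meta: DataFrame indexed by sample_id with donor, group, timepoint,
    marker and bmi columns.
    taxonomy: optional species taxonomy (index species_id).
    """

    frequencies: pd.DataFrame
    meta: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = self.frequencies.index.difference(self.meta.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {list(missing)[:3]}")

    def samples(self, group: str | None = None, timepoint: str | None = None,
                marker: str | None = None) -> pd.Index:
        m = self.meta.loc[self.frequencies.index]
        mask = pd.Series(True, index=m.index)
        if group is not None:
            mask &= m["group"] == group
        if timepoint is not None:
            mask &= m["timepoint"] == timepoint
        if marker is not None and "marker" in m.columns:
            mask &= m["marker"] == marker
        return m.index[mask]


def simpson_diversity(frequencies) -> float:
    """Simpson's index of diversity D = 1 - sum(p_i^2): the probability
    that two randomly drawn sequences of the sample belong to different
    species. Requires frequencies summing to 1."""
    p = np.asarray(frequencies, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies must sum to 1 (got {p.sum():.6f})")
    return float(1.0 - np.square(p).sum())


def richness(frequencies) -> int:
    """Number of species present (frequency strictly > 0)."""
    p = np.asarray(frequencies, dtype=float)
    return int((p > 0).sum())


def rollup_taxonomy(
    frequencies: pd.DataFrame, taxonomy: pd.DataFrame, rank: str
) -> pd.DataFrame:
    """Sum species frequencies within a taxonomic rank; row sums are
    preserved. rank='species' is the identity (columns renamed to the
    species labels of the taxonomy where available)."""
    if rank not in ("domain", "phylum", "family", "genus", "species"):
        raise ValueError(f"unknown rank: {rank}")
    labels = taxonomy[rank].reindex(frequencies.columns)
    if labels.isna().any():
        missing = list(frequencies.columns[labels.isna()])[:3]
        raise ValueError(f"species missing from taxonomy: {missing}")
    return frequencies.T.groupby(labels).sum().T


def group_specific_species(
    panel: GroupedFrequencyPanel,
    target_group: str = "RA",
    target_timepoints: tuple[str, ...] = ("T0",),
    excluded_group: str = "MetS",
    excluded_timepoints: tuple[str, ...] = ("T0", "T3"),
) -> tuple[list[str], dict[int, int]]:
    """Species present in >= 1 target-group sample (at the target
    timepoints) and absent from every excluded-group sample at the
    excluded timepoints.

    Returns the species list plus a carrier histogram mapping k to the
    number of selected species carried by exactly k target-group donors.
    """
    target_samples = [
        s for tp in target_timepoints for s in panel.samples(target_group, tp)
    ]
    excluded_samples = [
        s for tp in excluded_timepoints for s in panel.samples(excluded_group, tp)
    ]
    if not target_samples or not excluded_samples:
        raise ValueError("panel must contain samples of both groups")
    f = panel.frequencies
    in_target = (f.loc[target_samples] > 0).any(axis=0)
    in_excluded = (f.loc[excluded_samples] > 0).any(axis=0)
    selected = sorted(f.columns[in_target & ~in_excluded])
    donors = panel.meta.loc[target_samples, "donor"]
    histogram: dict[int, int] = {}
    for sp in selected:
        carriers = donors[(f.loc[target_samples, sp] > 0).to_numpy()].nunique()
        histogram[carriers] = histogram.get(carriers, 0) + 1
    return selected, histogram


def bmi_correlation_screen(
    panel: GroupedFrequencyPanel,
    timepoint: str = "T0",
    threshold: float = 0.4,
) -> pd.DataFrame:
    """Pearson correlation of each species' frequency with donor BMI
    across donors at one timepoint; species with |R| > threshold are
    flagged. A species with zero variance has undefined R, reported as 0
    and never flagged."""
    samples = panel.samples(timepoint=timepoint)
    if len(samples) < 3:
        raise ValueError("BMI screen needs at least 3 donors")
    f = panel.frequencies.loc[samples]
    bmi = panel.meta.loc[samples, "bmi"].to_numpy(dtype=float)
    bc = bmi - bmi.mean()
    X = f.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    denom = np.linalg.norm(Xc, axis=0) * np.linalg.norm(bc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc.T @ bc / denom, 0.0)
    out = pd.DataFrame(
        {"r": r, "flagged": np.abs(r) > threshold}, index=f.columns
    )
    out.index.name = "species_id"
    return out


def differential_species(
    panel: GroupedFrequencyPanel,
    group_a: str = "RA",
    group_b: str = "MetS",
    timepoints: tuple[str, ...] = ("T0", "T3"),
    p_threshold: float = 0.1,
) -> list[str]:
    """Species whose frequencies differ between groups (Welch, two-sided,
    p below threshold, pooling the given timepoints)."""
    sa = [s for tp in timepoints for s in panel.samples(group_a, tp)]
    sb = [s for tp in timepoints for s in panel.samples(group_b, tp)]
    out = []
    for sp in panel.frequencies.columns:
        try:
            res = welch_test(
                panel.frequencies.loc[sa, sp], panel.frequencies.loc[sb, sp]
            )
        except DegenerateDataError:
            continue
        if res.p < p_threshold:
            out.append(sp)
    return out


def donor_eukaryote_score(
    panel: GroupedFrequencyPanel,
    species: list[str],
    timepoints: tuple[str, ...] = ("T0", "T3"),
) -> pd.Series:
    """Per donor, the sum of the given species' frequencies across the
    given timepoints (additive over species and samples); donors with no
    sample containing any of the species score 0."""
    present = [s for s in species if s in panel.frequencies.columns]
    samples = [s for tp in timepoints for s in panel.samples(timepoint=tp)]
    donors = panel.meta.loc[samples, "donor"]
    if not present:
        return pd.Series(0.0, index=sorted(donors.unique()), name="eukaryote_score")
    sums = panel.frequencies.loc[samples, present].sum(axis=1)
    out = sums.groupby(donors).sum().sort_index()
    out.name = "eukaryote_score"
    return out
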