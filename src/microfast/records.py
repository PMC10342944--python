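"""Shared lightweight data containers used across pipeline stages.

These are deliberately thin wrappers around pandas/numpy objects: the
pipeline stages communicate through plain tables (FASTA/FASTQ, TSV, CSV)
and these classes only add the invariants and conveniences the stages need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Nucleotide alphabet used for one-hot encoding; 'N' absorbs every
#: non-ACGT symbol.
ALPHABET = "ACGTN"

TAXONOMY_RANKS = ("domain", "phylum", "family", "genus", "species")

#: Study timepoints: baseline, early fasting (day 3), end of fasting,
#: 3 days after breaking the fast.
TIMEPOINTS = ("T0", "T1", "T2", "T3")

MARKERS = ("16S", "ITS", "18S")


@dataclass
class ReferenceSet:
    """Local reference of species template sequences with taxonomy.

    taxonomy: DataFrame indexed by species_id with columns
        domain / phylum / family / genus / species
        (domain is 'prokaryote' or 'eukaryote').
    templates: species_id -> nucleotide template (all equal length, ACGT).
    """

    taxonomy: pd.DataFrame
    templates: dict[str, str]

    def __post_init__(self) -> None:
        if self.taxonomy.index.has_duplicates:
            raise ValueError("duplicate species_id in reference taxonomy")
        lengths = {len(t) for t in self.templates.values()}
        if len(lengths) > 1:
            raise ValueError("reference templates must all have equal length")
        bad = [s for s, t in self.templates.items() if set(t) - set("ACGT")]
        if bad:
            raise ValueError(f"non-ACGT symbols in templates: {bad[:3]}")

    @property
    def species_ids(self) -> list[str]:
        return list(self.taxonomy.index)

    @property
    def amplicon_length(self) -> int:
        return len(next(iter(self.templates.values())))

    def species_of_domain(self, domain: str) -> list[str]:
        return list(self.taxonomy.index[self.taxonomy["domain"] == domain])


@dataclass
class CohortDesign:
    """Cohort layout: donors with group labels and covariates.

    donors: DataFrame indexed by donor_id with columns
        group ('RA' or 'MetS'), bmi (kg/m^2), leukocyte_count (cells/nL).
    """

    donors: pd.DataFrame
    timepoints: tuple[str, ...] = TIMEPOINTS

    def __post_init__(self) -> None:
        if self.donors.index.has_duplicates:
            raise ValueError("duplicate donor_id in cohort design")
        if (self.donors["bmi"] <= 0).any():
            raise ValueError("BMI must be positive")

    @property
    def donor_ids(self) -> list[str]:
        return list(self.donors.index)

    def sample_ids(self, markers=("16S",)) -> list[str]:
        return [
            sample_name(d, t, m)
            for d in self.donor_ids
            for t in self.timepoints
            for m in markers
        ]


def sample_name(donor: str, timepoint: str, marker: str) -> str:
    return f"{donor}.{timepoint}.{marker}"


def split_sample_name(sample_id: str) -> tuple[str, str, str]:
    donor, timepoint, marker = sample_id.split(".")
    return donor, timepoint, marker


@dataclass
class CompositionSet:
    """Ground-truth per-sample species frequencies.

    frequencies: DataFrame samples x species (rows sum to 1).
    meta: DataFrame indexed by sample_id with donor/group/timepoint/marker/bmi.
    """

    frequencies: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.frequencies.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("composition rows must sum to 1")


@dataclass
class ReadSet:
    """Fixed-marker amplicon reads of one sample.

    true_species carries the species of origin of each read when the reads
    were simulated; pipeline stages never consume it — it exists only so
    that recovery tests can compare against the generator's ground truth.
    """

    sample_id: str
    marker: str
    ids: list[str]
    sequences: list[str]
    true_species: list[str] | None = None
    qualities: list[str] | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.sequences)
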