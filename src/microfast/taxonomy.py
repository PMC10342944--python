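"""Taxonomy assignment of cluster representatives by local alignment.

Each cluster's representative sequence is aligned against every template
of a local species reference (Smith-Waterman local alignment, +1 match,
-1 mismatch, affine gaps -2 open / -1 extend — chosen to mimic default
nucleotide-search behaviour). The best-scoring species wins (ties broken
toward the lexicographically smallest species_id); clusters whose best
alignment spans fewer than 200 columns are dropped from downstream
counting. Species counts are the summed sizes of their clusters, and
per-sample frequencies are counts divided by the total size of all
selected (filter-passing) clusters of that sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from .records import ReferenceSet
from .som import EncodedReads, ReadCluster, ReadClusterSet

logger = logging.getLogger(__name__)


class EmptySampleError(ValueError):
    """Raised when no cluster of a sample survives the alignment filter."""


@dataclass
class AlignmentHit:
    representative_id: str
    species_id: str
    score: float
    length: int  # alignment columns including gaps
    identity: float  # matches / columns

    def __post_init__(self) -> None:
        if self.length < 0 or not 0 <= self.identity <= 1:
            raise ValueError("invalid alignment hit")


def _make_aligner(match, mismatch, gap_open, gap_extend) -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="local",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=gap_open,
        extend_gap_score=gap_extend,
    )


def align_local(
    query: str,
    target: str,
    match: float = 1,
    mismatch: float = -1,
    gap_open: float = -2,
    gap_extend: float = -1,
) -> AlignmentHit:
    """Optimal local alignment of query against target.

    Returns score, alignment length (columns including gaps) and identity
    (matches / columns). Of co-optimal alignments the aligner's first is
    taken (deterministic).
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(query, target)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / length if length else 0.0
    return AlignmentHit(
        representative_id="query",
        species_id="target",
        score=float(aln.score),
        length=int(length),
        identity=float(identity),
    )


class TaxonomyAssigner:
    """Best-hit species assigner over a fixed reference (fit/predict style).

    fit(reference) stores the templates; predict(sequences) returns the
    best AlignmentHit per sequence or None where the best alignment is
    shorter than `min_alignment_length`.
    """

    def __init__(
        self,
        min_alignment_length: int = 200,
        match: float = 1,
        mismatch: float = -1,
        gap_open: float = -2,
        gap_extend: float = -1,
    ):
        self.min_alignment_length = min_alignment_length
        self.match = match
        self.mismatch = mismatch
        self.gap_open = gap_open
        self.gap_extend = gap_extend

    def get_params(self, deep: bool = True) -> dict:
        return {
            "min_alignment_length": self.min_alignment_length,
            "match": self.match,
            "mismatch": self.mismatch,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
        }

    def set_params(self, **params) -> "TaxonomyAssigner":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, reference: ReferenceSet) -> "TaxonomyAssigner":
        if not reference.templates:
            raise ValueError("empty reference")
        self.reference_ = reference
        self._aligner = _make_aligner(
            self.match, self.mismatch, self.gap_open, self.gap_extend
        )
        # sorted so that score ties resolve to the smallest species_id
        self._targets = sorted(reference.templates.items())
        return self

    def best_hit(self, sequence: str, rep_id: str = "query") -> AlignmentHit | None:
        """Best-scoring species for one sequence, None if filtered out."""
        best: AlignmentHit | None = None
        for species_id, template in self._targets:
            aln = self._aligner.align(sequence, template)[0]
            if best is not None and aln.score <= best.score:
                continue
            counts = aln.counts()
            length = counts.identities + counts.mismatches + counts.gaps
            best = AlignmentHit(
                representative_id=rep_id,
                species_id=species_id,
                score=float(aln.score),
                length=int(length),
                identity=counts.identities / length if length else 0.0,
            )
        if best is None or best.length < self.min_alignment_length:
            return None
        return best

    def predict(self, sequences) -> list[AlignmentHit | None]:
        return [self.best_hit(s, f"q{i}") for i, s in enumerate(sequences)]


@dataclass
class AssignedCluster:
    cluster: ReadCluster
    hit: AlignmentHit | None  # None: dropped by the alignment-length filter

    @property
    def selected(self) -> bool:
        return self.hit is not None


def assign_clusters(
    clusterset: ReadClusterSet,
    encoded: EncodedReads,
    reference: ReferenceSet,
    min_alignment_length: int = 200,
    **scoring,
) -> list[AssignedCluster]:
    """Align every cluster representative to the reference and attach the
    best hit; clusters failing the alignment-length filter keep hit=None
    (their reads are excluded from frequency denominators)."""
    assigner = TaxonomyAssigner(
        min_alignment_length=min_alignment_length, **scoring
    ).fit(reference)
    out = []
    n_dropped = 0
    for cl in clusterset.clusters:
        if cl.representative is None:
            raise ValueError("representatives must be selected before assignment")
        seq = "".join(
            "ACGTN"[b] for b in encoded.codes[cl.representative]
        )
        hit = assigner.best_hit(seq, rep_id=encoded.ids[cl.representative])
        if hit is None:
            n_dropped += 1
        out.append(AssignedCluster(cluster=cl, hit=hit))
    if n_dropped:
        logger.info(
            "alignment filter dropped %d/%d clusters", n_dropped, len(out)
        )
    return out


@dataclass
class SpeciesFrequencyTable:
    """Per-sample species counts and relative frequencies.

    counts: DataFrame samples x species (summed selected-cluster sizes);
    frequencies: counts normalized per sample (rows sum to 1);
    taxonomy: optional reference taxonomy for rollups.
    """

    counts: pd.DataFrame
    frequencies: pd.DataFrame
    taxonomy: pd.DataFrame | None = field(default=None)

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def species_counts(assigned: list[AssignedCluster]) -> dict[str, int]:
    """Selected-cluster sizes summed per species for one sample."""
    counts: dict[str, int] = {}
    for ac in assigned:
        if ac.hit is None:
            continue
        counts[ac.hit.species_id] = counts.get(ac.hit.species_id, 0) + ac.cluster.size
    return counts


def build_frequency_table(
    per_sample_counts: dict[str, dict[str, int]],
    taxonomy: pd.DataFrame | None = None,
) -> SpeciesFrequencyTable:
    """Sample x species frequency table from per-sample species counts.

    Frequencies divide each species count by the total count of sequences
    in selected clusters of that sample. A sample with zero selected
    clusters is an error (it has no defined frequencies).
    """
    empty = [s for s, c in per_sample_counts.items() if not c or sum(c.values()) == 0]
    if empty:
        raise EmptySampleError(f"no selected clusters in samples: {empty}")
    counts = (
        pd.DataFrame.from_dict(per_sample_counts, orient="index")
        .fillna(0)
        .astype(int)
        .sort_index(axis=1)
    )
    counts.index.name = "sample_id"
    frequencies = counts.div(counts.sum(axis=1), axis=0)
    return SpeciesFrequencyTable(
        counts=counts, frequencies=frequencies, taxonomy=taxonomy
    )
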