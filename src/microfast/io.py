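"""File formats: FASTA/FASTQ read sets (gzip transparent), reference
FASTA + taxonomy TSV, and the tabular TSV/CSV contracts between stages."""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import ReadSet, ReferenceSet


class ParseError(ValueError):
    pass


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path, sample_id: str | None = None, marker: str = "16S") -> ReadSet:
    """Read a FASTA file into a ReadSet (order preserved)."""
    path = Path(path)
    with _open_text(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    return ReadSet(
        sample_id=sample_id or path.stem,
        marker=marker,
        ids=[r.id for r in records],
        sequences=[str(r.seq).upper() for r in records],
    )


def read_fastq(path, sample_id: str | None = None, marker: str = "16S") -> ReadSet:
    """Read a FASTQ file; qualities are parsed but ignored downstream."""
    path = Path(path)
    ids, seqs, quals = [], [], []
    try:
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                ids.append(rec.id)
                seqs.append(str(rec.seq).upper())
                quals.append(rec.letter_annotations["phred_quality"])
    except ValueError as e:  # Biopython reports truncated/malformed records
        raise ParseError(f"{path}: {e}") from e
    return ReadSet(
        sample_id=sample_id or path.stem,
        marker=marker,
        ids=ids,
        sequences=seqs,
        qualities=quals,
    )


def write_fasta(reads: ReadSet | list[tuple[str, str]], path) -> None:
    items = (
        list(zip(reads.ids, reads.sequences)) if isinstance(reads, ReadSet) else reads
    )
    with _open_text(path, "wt") as fh:
        SeqIO.write(
            (SeqRecord(Seq(s), id=i, description="") for i, s in items), fh, "fasta"
        )


def write_fastq(reads: ReadSet, path, quality: int = 35) -> None:
    """Write reads as FASTQ with a constant quality score."""
    with _open_text(path, "wt") as fh:
        for i, s in zip(reads.ids, reads.sequences):
            rec = SeqRecord(Seq(s), id=i, description="")
            rec.letter_annotations["phred_quality"] = [quality] * len(s)
            SeqIO.write(rec, fh, "fastq")


def write_reference(reference: ReferenceSet, fasta_path, taxonomy_path) -> None:
    write_fasta(
        [(sid, reference.templates[sid]) for sid in reference.species_ids],
        fasta_path,
    )
    reference.taxonomy.to_csv(taxonomy_path, sep="\t")


def read_reference(fasta_path, taxonomy_path) -> ReferenceSet:
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col="species_id")
    with _open_text(fasta_path) as fh:
        templates = {r.id: str(r.seq).upper() for r in SeqIO.parse(fh, "fasta")}
    missing = set(taxonomy.index) - set(templates)
    if missing:
        raise ParseError(f"taxonomy species without templates: {sorted(missing)[:3]}")
    return ReferenceSet(taxonomy=taxonomy, templates=templates)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tsv.gz")) else ","
    df.to_csv(path, sep=sep, index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tsv.gz")) else ","
    return pd.read_csv(path, sep=sep, index_col=index_col)


def clusters_to_frame(clusterset, encoded) -> pd.DataFrame:
    """Cluster table: id, size, cohesion, representative id + sequence."""
    rows = []
    for cl in clusterset.clusters:
        rep = cl.representative
        rows.append(
            {
                "cluster_id": cl.cluster_id,
                "n_members": cl.size,
                "cohesion": cl.cohesion,
                "is_subcluster": cl.is_subcluster,
                "representative_id": encoded.ids[rep] if rep is not None else None,
                "representative_sequence": (
                    "".join("ACGTN"[b] for b in encoded.codes[rep])
                    if rep is not None
                    else None
                ),
            }
        )
    return pd.DataFrame(rows)
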