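"""End-to-end pipeline: simulate -> cluster -> assign -> metrics ->
pathways -> immune -> clinical, with a YAML-round-trippable configuration
and a manifest recording seeds and per-stage output hashes.

Every stochastic stage derives its seed deterministically from the single
top-level seed, so rerunning the same configuration reproduces identical
outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, io, pathways, som, stats, synthetic, taxonomy
from .clinical import cohort_summary, load_table1
from .records import split_sample_name


class DependencyError(RuntimeError):
    """A stage's upstream artifact is missing."""


@dataclass
class PipelineConfig:
    """Parameters of every stage, with one top-level seed."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    # synthetic scenario
    n_species: int = 20
    amplicon_length: int = 200
    divergence: float = 0.2
    n_ra: int = 4
    n_mets: int = 3
    markers: tuple[str, ...] = ("16S",)
    timepoints: tuple[str, ...] = ("T0", "T3")
    depth: int = 2000
    substitution_rate: float = 0.005
    n_pathways: int = 40
    pathway_bias: float = 0.3
    # clustering
    grid: tuple[int, int] = (20, 20)
    rounds: int = 10_000
    cohesion_threshold: float = 0.95
    subgrid: tuple[int, int] = (10, 10)
    subrounds: int = 10_000
    # assignment
    min_alignment_length: int = 200
    # statistics
    alpha: float = 0.05
    n_cytometry_populations: int = 30

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k in ("markers", "timepoints", "grid", "subgrid"):
            d[k] = list(d[k])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("markers", "timepoints", "grid", "subgrid"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _seed_for(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full synthetic-study pipeline and write all artifacts.

    Returns the output directory. The manifest lists each stage's seed
    and the hash of every file written, so identical configs can be
    verified to reproduce identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    # --- simulate ---------------------------------------------------------
    s = _seed_for(config.seed, "reference")
    reference = synthetic.generate_reference(
        config.n_species,
        config.amplicon_length,
        config.divergence,
        seed=s,
    )
    io.write_reference(reference, out / "reference.fasta", out / "taxonomy.tsv")
    manifest["stages"]["reference"] = s

    design = synthetic.generate_cohort(
        n_ra=config.n_ra,
        n_mets=config.n_mets,
        seed=_seed_for(config.seed, "cohort"),
        timepoints=config.timepoints,
    )
    design.donors.to_csv(out / "design.csv")

    comp = synthetic.generate_composition(
        design,
        reference,
        seed=_seed_for(config.seed, "composition"),
        markers=config.markers,
        timepoints=config.timepoints,
    )
    io.write_table(comp.frequencies, out / "true_composition.tsv")
    io.write_table(comp.meta, out / "sample_meta.tsv")

    db = synthetic.generate_pathway_db(
        reference,
        n_pathways=config.n_pathways,
        seed=_seed_for(config.seed, "pathways"),
        phylum_bias=config.pathway_bias,
    )
    io.write_table(db.scores, out / "pathway_scores_db.tsv")
    io.write_table(db.hierarchy, out / "pathway_hierarchy.tsv")

    reads_dir = out / "reads"
    reads_dir.mkdir(exist_ok=True)
    readsets = {}
    for sample_id in comp.frequencies.index:
        rs = synthetic.simulate_reads(
            comp.frequencies.loc[sample_id],
            reference,
            depth=config.depth,
            substitution_rate=config.substitution_rate,
            seed=_seed_for(config.seed, f"reads:{sample_id}"),
            sample_id=sample_id,
            marker=split_sample_name(sample_id)[2],
        )
        io.write_fasta(rs, reads_dir / f"{sample_id}.fasta")
        readsets[sample_id] = rs

    # --- cluster + assign -------------------------------------------------
    per_sample_counts = {}
    cluster_frames = []
    for sample_id, rs in readsets.items():
        encoded = som.encode_reads(rs, length=config.amplicon_length)
        clusterset = som.cluster_sample(
            encoded,
            grid=config.grid,
            rounds=config.rounds,
            cohesion_threshold=config.cohesion_threshold,
            subgrid=config.subgrid,
            subrounds=config.subrounds,
            seed=_seed_for(config.seed, f"som:{sample_id}"),
        )
        assigned = taxonomy.assign_clusters(
            clusterset,
            encoded,
            reference,
            min_alignment_length=config.min_alignment_length,
        )
        per_sample_counts[sample_id] = taxonomy.species_counts(assigned)
        frame = io.clusters_to_frame(clusterset, encoded)
        frame.insert(0, "sample_id", sample_id)
        cluster_frames.append(frame)
    pd.concat(cluster_frames).to_csv(out / "clusters.tsv", sep="\t", index=False)

    freq_table = taxonomy.build_frequency_table(
        per_sample_counts, taxonomy=reference.taxonomy
    )
    io.write_table(freq_table.frequencies, out / "species_frequencies.tsv")
    io.write_table(freq_table.counts, out / "species_counts.tsv")

    # --- community metrics ------------------------------------------------
    panel = community.GroupedFrequencyPanel(
        frequencies=freq_table.frequencies,
        meta=comp.meta.loc[freq_table.frequencies.index],
        taxonomy=reference.taxonomy,
    )
    metrics = pd.DataFrame(
        {
            "simpson": freq_table.frequencies.apply(simpson_row, axis=1),
            "richness": freq_table.frequencies.apply(community.richness, axis=1),
        }
    )
    io.write_table(metrics, out / "community_metrics.tsv")
    io.write_table(
        community.rollup_taxonomy(
            freq_table.frequencies, reference.taxonomy, "phylum"
        ),
        out / "phylum_frequencies.tsv",
    )

    # --- pathway scores ---------------------------------------------------
    pst = pathways.sample_pathway_scores(freq_table.frequencies, db)
    io.write_table(pst.scores, out / "sample_pathway_scores.tsv")
    io.write_table(
        pathways.group_shift_summary(pst, panel.meta),
        out / "pathway_shift_summary.tsv",
        index=False,
    )

    # --- immune profile ---------------------------------------------------
    cyto_design = synthetic.generate_cohort(
        n_ra=20,
        n_mets=10,
        seed=_seed_for(config.seed, "cyto_cohort"),
        timepoints=("T0", "T1", "T2", "T3"),
    )
    cyto = synthetic.generate_cytometry_table(
        cyto_design,
        n_populations=config.n_cytometry_populations,
        seed=_seed_for(config.seed, "cytometry"),
    )
    profile = stats.significance_profile(cyto, alpha=config.alpha)
    io.write_table(profile, out / "significance_profile.tsv")

    # --- clinical ---------------------------------------------------------
    summary = cohort_summary(load_table1())
    (out / "clinical_summary.json").write_text(json.dumps(summary, indent=2))

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(out))] = _hash_file(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def simpson_row(row: pd.Series) -> float:
    return community.simpson_diversity(row.to_numpy())
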