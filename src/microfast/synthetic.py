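"""Synthetic study-data generator with known ground truth.

Emulates every input the analysis pipeline consumes: a local species
reference (templates + taxonomy), per-sample true compositions with
fasting-induced phylum shifts and rare RA-specific species, error-bearing
amplicon reads, a pathway-score database with a phylum bias, clinical
component tables and cytometric population tables with injected group/time
effects. Ground truth (the read -> species map, the true compositions, the
identity of the effect-bearing population) is stored alongside the outputs
for recovery tests but is never consumed by pipeline stages.

Error model: i.i.d. substitutions only. The clustering stage operates on
fixed-length reads, so indels are deliberately out of scope (a documented
limitation of the generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import (
    TIMEPOINTS,
    CohortDesign,
    CompositionSet,
    ReadSet,
    ReferenceSet,
    sample_name,
)

BACTERIAL_PHYLA = (
    "Firmicutes",
    "Bacteroidetes",
    "Proteobacteria",
    "Actinobacteria",
    "Verrucomicrobia",
)
EUKARYOTE_PHYLUM = "Ascomycota"

#: Fasting-induced T3/T0 phylum multipliers emulating the observed shift:
#: Actinobacteria and Firmicutes decrease, Bacteroidetes and Verrucomicrobia
#: increase, Proteobacteria increase moderately.
DEFAULT_PHYLUM_MULTIPLIERS = {
    "Firmicutes": 0.6,
    "Bacteroidetes": 1.8,
    "Proteobacteria": 1.4,
    "Actinobacteria": 0.6,
    "Verrucomicrobia": 1.8,
    EUKARYOTE_PHYLUM: 1.0,
}

#: Frequency of rare RA-specific species (the "<1 out of 10^3" regime).
DEFAULT_RARE_FREQUENCY = 5e-4


def _child_seeds(seed: int | None, n: int) -> list[int]:
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


def _mutations_per_species(divergence: float, length: int) -> int:
    """Mutation count from the ancestor so that the expected *pairwise*
    Hamming distance between two same-genus templates equals
    divergence * length.

    With k uniformly placed mutations per species (each to one of the
    three other bases), E[pairwise mismatches] = 2k - (4/3)k^2/L; inverting
    the quadratic gives k. Saturates at full randomization for
    divergence >= 3/4.
    """
    d = min(divergence, 0.7499)
    k = (3.0 * length / 4.0) * (1.0 - np.sqrt(1.0 - 4.0 * d / 3.0))
    return max(1, int(round(k)))


def generate_reference(
    n_species: int,
    amplicon_length: int = 200,
    within_genus_divergence: float = 0.2,
    seed: int | None = None,
    eukaryote_fraction: float = 0.25,
    genus_size: int = 2,
) -> ReferenceSet:
    """Generate species templates plus a five-rank taxonomy.

    Species are grouped into genera (`genus_size` consecutive species per
    genus); genera get independent random ancestors, so templates of
    different genera diverge at ~75% of positions, far above the
    within-genus expectation of within_genus_divergence * length.
    Bacterial genera cycle through the five gut phyla; a trailing block of
    ~`eukaryote_fraction` of the species is eukaryotic (single fungal
    phylum), giving the eukaryote markers a smaller species pool.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if not 0 < within_genus_divergence <= 1:
        raise ValueError("within_genus_divergence must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_euk = int(round(n_species * eukaryote_fraction)) if n_species >= 4 else 0
    n_bact = n_species - n_euk

    k = _mutations_per_species(within_genus_divergence, amplicon_length)
    bases = np.arange(4, dtype=np.uint8)

    rows = []
    templates: dict[str, str] = {}
    genus_counter = 0
    ancestor: np.ndarray | None = None
    for i in range(n_species):
        # a genus never straddles the prokaryote/eukaryote boundary
        if i % genus_size == 0 or i == n_bact:
            ancestor = rng.integers(0, 4, size=amplicon_length, dtype=np.uint8)
            genus_counter += 1
        tpl = ancestor.copy()
        pos = rng.choice(amplicon_length, size=k, replace=False)
        shift = rng.integers(1, 4, size=k, dtype=np.uint8)
        tpl[pos] = (tpl[pos] + shift) % 4
        is_euk = i >= n_bact
        if is_euk:
            domain, phylum = "eukaryote", EUKARYOTE_PHYLUM
        else:
            domain = "prokaryote"
            phylum = BACTERIAL_PHYLA[(genus_counter - 1) % len(BACTERIAL_PHYLA)]
        sid = f"sp_{i:03d}"
        rows.append(
            {
                "species_id": sid,
                "domain": domain,
                "phylum": phylum,
                "family": f"fam_{(genus_counter - 1) // 2:02d}",
                "genus": f"gen_{genus_counter - 1:02d}",
                "species": f"{phylum[:4]}_{i:03d}",
            }
        )
        templates[sid] = "".join("ACGT"[b] for b in tpl)
    taxonomy = pd.DataFrame(rows).set_index("species_id")
    return ReferenceSet(taxonomy=taxonomy, templates=templates)


def generate_cohort(
    n_ra: int = 20,
    n_mets: int = 10,
    seed: int | None = None,
    timepoints: tuple[str, ...] = TIMEPOINTS,
) -> CohortDesign:
    """RA and MetS donors with BMI and leukocyte counts.

    MetS BMI centers near 35 kg/m^2 and RA near 25 (the groups differed
    markedly in the emulated study); leukocyte counts ~4-10 cells/nL.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_ra):
        rows.append(
            {
                "donor_id": f"RA_{i + 1:02d}",
                "group": "RA",
                "bmi": float(np.round(rng.normal(25.0, 4.0), 1)),
                "leukocyte_count": float(np.round(rng.uniform(4.0, 10.0), 2)),
            }
        )
    for i in range(n_mets):
        rows.append(
            {
                "donor_id": f"MetS_{i + 1:02d}",
                "group": "MetS",
                "bmi": float(np.round(rng.normal(35.0, 4.0), 1)),
                "leukocyte_count": float(np.round(rng.uniform(4.0, 10.0), 2)),
            }
        )
    donors = pd.DataFrame(rows).set_index("donor_id")
    donors["bmi"] = donors["bmi"].clip(lower=16.0)
    return CohortDesign(donors=donors, timepoints=timepoints)


@dataclass
class EffectConfig:
    """Injected effects for composition generation."""

    phylum_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHYLUM_MULTIPLIERS)
    )
    rare_frequency: float = DEFAULT_RARE_FREQUENCY
    dirichlet_concentration: float = 2.0
    #: donors (RA) carrying rare group-specific species at T0; species are
    #: drawn from the reference's last bacterial genus
    rare_carriers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.phylum_multipliers.values()):
            raise ValueError("phylum multipliers must be positive")


def generate_composition(
    design: CohortDesign,
    reference: ReferenceSet,
    effect: EffectConfig | None = None,
    seed: int | None = None,
    markers: tuple[str, ...] = ("16S",),
    timepoints: tuple[str, ...] = ("T0", "T3"),
) -> CompositionSet:
    """True species frequencies per donor x timepoint x marker.

    Each donor draws a baseline Dirichlet composition over the species of
    the marker's domain (16S: prokaryotes; ITS/18S: eukaryotes, i.e. a
    smaller pool). T3 frequencies are the baseline reweighted by per-phylum
    multipliers and renormalized. Rare RA-specific species (configured per
    donor) are spiked into RA T0 samples at `rare_frequency` and appear in
    no other sample.
    """
    effect = effect or EffectConfig()
    rng = np.random.default_rng(seed)
    tax = reference.taxonomy
    all_species = list(tax.index)
    unknown = [
        s for carriers in effect.rare_carriers.values() for s in carriers
        if s not in tax.index
    ]
    if unknown:
        raise ValueError(f"unknown species in rare_carriers: {unknown}")

    rare_species = sorted({s for v in effect.rare_carriers.values() for s in v})
    freq_rows = {}
    meta_rows = []
    for donor in design.donor_ids:
        group = design.donors.loc[donor, "group"]
        for marker in markers:
            domain = "prokaryote" if marker == "16S" else "eukaryote"
            pool = [
                s
                for s in tax.index[tax["domain"] == domain]
                if s not in rare_species
            ]
            if not pool:
                raise ValueError(f"reference has no {domain} species for {marker}")
            base = rng.dirichlet(
                np.full(len(pool), effect.dirichlet_concentration)
            )
            for tp in timepoints:
                freq = pd.Series(0.0, index=all_species)
                mult = np.array(
                    [
                        effect.phylum_multipliers.get(tax.loc[s, "phylum"], 1.0)
                        if tp == "T3"
                        else 1.0
                        for s in pool
                    ]
                )
                w = base * mult
                freq.loc[pool] = w / w.sum()
                carried = effect.rare_carriers.get(donor, [])
                if tp == "T0" and group == "RA" and carried and marker == "16S":
                    spike = effect.rare_frequency
                    freq *= 1.0 - spike * len(carried)
                    freq.loc[carried] = spike
                sid = sample_name(donor, tp, marker)
                freq_rows[sid] = freq / freq.sum()
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "donor": donor,
                        "group": group,
                        "timepoint": tp,
                        "marker": marker,
                        "bmi": design.donors.loc[donor, "bmi"],
                    }
                )
    frequencies = pd.DataFrame(freq_rows).T
    frequencies.index.name = "sample_id"
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return CompositionSet(frequencies=frequencies, meta=meta)


def simulate_reads(
    composition: pd.Series,
    reference: ReferenceSet,
    depth: int = 2000,
    substitution_rate: float = 0.005,
    seed: int | None = None,
    sample_id: str = "sample",
    marker: str = "16S",
) -> ReadSet:
    """Draw `depth` reads from a composition and add i.i.d. substitutions.

    Each read is a copy of its species template with every position
    independently substituted (to one of the three other bases) with
    probability `substitution_rate`. The species of origin is recorded as
    hidden ground truth.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= substitution_rate < 0.5:
        raise ValueError("substitution_rate must be in [0, 0.5)")
    comp = composition[composition > 0]
    unknown = [s for s in comp.index if s not in reference.templates]
    if unknown:
        raise ValueError(f"unknown species in composition: {unknown[:3]}")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, (comp / comp.sum()).to_numpy())
    L = reference.amplicon_length
    code = {c: i for i, c in enumerate("ACGT")}
    ids, seqs, truth = [], [], []
    r = 0
    for species, n in zip(comp.index, counts):
        if n == 0:
            continue
        tpl = np.fromiter(
            (code[c] for c in reference.templates[species]), dtype=np.uint8, count=L
        )
        reads = np.tile(tpl, (n, 1))
        if substitution_rate > 0:
            mask = rng.random((n, L)) < substitution_rate
            shift = rng.integers(1, 4, size=mask.sum(), dtype=np.uint8)
            reads[mask] = (reads[mask] + shift) % 4
        for row in reads:
            ids.append(f"{sample_id}:read_{r:06d}")
            seqs.append("".join("ACGT"[b] for b in row))
            truth.append(species)
            r += 1
    # restore a reproducible interleaved order (reads arrive shuffled)
    order = rng.permutation(depth)
    return ReadSet(
        sample_id=sample_id,
        marker=marker,
        ids=[ids[i] for i in order],
        sequences=[seqs[i] for i in order],
        true_species=[truth[i] for i in order],
    )


H1_CATEGORIES = ("biosynthesis", "degradation", "energy", "other")
H2_BY_H1 = {
    "biosynthesis": ("amino_acids", "cofactors", "nucleotides", "lipids"),
    "degradation": ("carbohydrates", "amines"),
    "energy": ("fermentation", "respiration"),
    "other": ("misc",),
}

#: Phyla whose species carry elevated biosynthesis scores by default,
#: making the generalist-shift pattern recoverable.
BIASED_PHYLA = ("Bacteroidetes", "Proteobacteria")


def generate_pathway_db(
    reference: ReferenceSet,
    n_pathways: int = 40,
    seed: int | None = None,
    phylum_bias: float = 0.3,
):
    """Species x pathway scores in [0,1] with a two-level hierarchy.

    Pathways cycle through the H1 categories; with phylum_bias > 0,
    Bacteroidetes/Proteobacteria species get their biosynthesis (and, at
    half strength, degradation/energy) scores shifted up, so that the
    increasing phyla carry broader metabolic annotations.
    """
    from .pathways import PathwayDB

    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    rng = np.random.default_rng(seed)
    h1 = [H1_CATEGORIES[i % len(H1_CATEGORIES)] for i in range(n_pathways)]
    h2 = [H2_BY_H1[c][i % len(H2_BY_H1[c])] for i, c in enumerate(h1)]
    pathway_ids = [f"pwy_{i:03d}" for i in range(n_pathways)]
    hierarchy = pd.DataFrame(
        {"h1": h1, "h2": h2}, index=pd.Index(pathway_ids, name="pathway_id")
    )
    species = reference.species_ids
    scores = rng.uniform(0.1, 0.7, size=(len(species), n_pathways))
    if phylum_bias:
        biased_rows = reference.taxonomy["phylum"].isin(BIASED_PHYLA).to_numpy()
        h1_arr = np.array(h1)
        bias_cols = np.where(
            h1_arr == "biosynthesis",
            phylum_bias,
            np.where(np.isin(h1_arr, ("degradation", "energy")), phylum_bias / 2, 0.0),
        )
        scores[biased_rows] += bias_cols[None, :]
    scores = np.clip(scores, 0.0, 1.0)
    table = pd.DataFrame(
        scores, index=pd.Index(species, name="species_id"), columns=pathway_ids
    )
    return PathwayDB(scores=table, hierarchy=hierarchy)


@dataclass
class ClinicalEffect:
    """Multiplicative per-timepoint improvement applied to RA inflammatory
    components (1.0 = stationary)."""

    multipliers: dict[str, float] = field(
        default_factory=lambda: {"T0": 1.0, "T1": 0.85, "T2": 0.7, "T3": 0.55}
    )


def generate_clinical_components(
    design: CohortDesign,
    effect: ClinicalEffect | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per donor x timepoint DAS28/SDAI component table.

    Columns: tjc28, sjc28 (integers 0-28), esr (mm/h, > 0), crp (mg/dL),
    gh (0-100 mm), pga, ega (0-10 cm). RA components improve
    multiplicatively over timepoints per `effect`; MetS components carry no
    joint involvement and stay stationary in expectation.
    """
    effect = effect or ClinicalEffect()
    rng = np.random.default_rng(seed)
    rows = []
    for donor in design.donor_ids:
        group = design.donors.loc[donor, "group"]
        base_tjc = rng.poisson(6) if group == "RA" else 0
        base_sjc = rng.poisson(4) if group == "RA" else 0
        base_esr = rng.lognormal(np.log(25 if group == "RA" else 10), 0.4)
        base_crp = rng.lognormal(np.log(1.0 if group == "RA" else 0.3), 0.5)
        base_gh = rng.uniform(30, 80) if group == "RA" else rng.uniform(0, 30)
        for tp in design.timepoints:
            m = effect.multipliers.get(tp, 1.0) if group == "RA" else 1.0
            noise = rng.lognormal(0.0, 0.08, size=5)
            rows.append(
                {
                    "donor": donor,
                    "group": group,
                    "timepoint": tp,
                    "tjc28": int(min(28, round(base_tjc * m * noise[0]))),
                    "sjc28": int(min(28, round(base_sjc * m * noise[1]))),
                    "esr": max(1.0, base_esr * m * noise[2]),
                    "crp": max(0.0, base_crp * m * noise[3]),
                    "gh": float(np.clip(base_gh * m * noise[4], 0, 100)),
                    "pga": float(np.clip(base_gh * m * noise[4] / 10.0, 0, 10)),
                    "ega": float(np.clip(base_gh * m * noise[0] / 12.0, 0, 10)),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CytometryEffect:
    """Injected effect on one designated leukocyte population: an RA
    baseline deficit relative to MetS and an increase during fasting,
    emulating the non-classical monocyte kinetics."""

    target_population: str = "pop_000"
    ra_baseline_factor: float = 0.5  # RA T0 level relative to MetS
    fasting_factors: dict[str, float] = field(
        default_factory=lambda: {"T0": 1.0, "T1": 1.6, "T2": 2.0, "T3": 1.8}
    )


def generate_cytometry_table(
    design: CohortDesign,
    n_populations: int = 110,
    effect: CytometryEffect | None = None,
    seed: int | None = None,
    noise_sd: float = 0.25,
):
    """Population x sample leukocyte fraction table with one effect-bearing
    population (pass ``effect=CytometryEffect(ra_baseline_factor=1,
    fasting_factors={})`` for a pure null table).

    Returns a PopulationCountTable with per-sample fractions summing to 1
    and the design's leukocyte counts attached.
    """
    from .stats import PopulationCountTable

    effect = effect or CytometryEffect()
    rng = np.random.default_rng(seed)
    pops = [f"pop_{i:03d}" for i in range(n_populations)]
    base_means = rng.dirichlet(np.full(n_populations, 5.0))
    rows = {}
    meta_rows = []
    for donor in design.donor_ids:
        group = design.donors.loc[donor, "group"]
        donor_shift = rng.lognormal(0.0, 0.1, size=n_populations)
        for tp in design.timepoints:
            level = base_means * donor_shift * rng.lognormal(
                0.0, noise_sd, size=n_populations
            )
            if effect.target_population in pops:
                ti = pops.index(effect.target_population)
                f = effect.fasting_factors.get(tp, 1.0)
                if group == "RA":
                    level[ti] *= effect.ra_baseline_factor * f
            sid = sample_name(donor, tp, "FACS")
            rows[sid] = level / level.sum()
            meta_rows.append(
                {
                    "sample_id": sid,
                    "donor": donor,
                    "group": group,
                    "timepoint": tp,
                    "leukocyte_count": design.donors.loc[donor, "leukocyte_count"],
                }
            )
    fractions = pd.DataFrame(rows, index=pops).T
    fractions.index.name = "sample_id"
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return PopulationCountTable(fractions=fractions, meta=meta)
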