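# Methods

This note documents the models and procedures implemented in `microfast`,
the parameters that matter, the design choices made where several
reasonable options existed, and what the synthetic-data generator does and
does not emulate.

## Study setting

The package targets a fasting-intervention design: RA patients (and a
non-inflammatory metabolic-syndrome control group) are monitored at
baseline (T0), early fasting (T1), end of fasting (T2) and three days
after breaking the fast (T3). Stool samples at T0/T3 are sequenced with
16S (prokaryotes), ITS (fungi) and 18S (eukaryotes) amplicons; blood
leukocytes are profiled cytometrically at all four timepoints; disease
activity is scored with DAS28-ESR and SDAI.

## SOM read clustering

Reads are one-hot encoded over the alphabet {A, C, G, T, N} at a fixed
nominal length (default 200 nt): shorter reads are discarded (counted),
longer reads truncated, and any non-ACGT symbol maps to the N indicator.
Node profiles are real-valued position-weight matrices rather than
discrete sequences — a strictly discrete codebook would make the SOM
update rule ill-defined — and the read-node distance is the soft Hamming
distance `d = Σ_pos (1 − w[pos, base])`. When a profile is one-hot this
equals the integer Hamming distance to the profile's consensus, so the
discrete distance is recovered as a special case (this identity is
asserted in the tests).

Training presents one uniformly sampled read per round; the default
10,000 rounds are therefore 10,000 single-read presentations. Nodes are
initialized from reads sampled with replacement. The learning rate decays
linearly 0.5 → 0.01 and the Gaussian neighborhood radius linearly
max(grid)/2 → 0.5 over the rounds; these schedules are conventional SOM
defaults, fixed here and exposed as parameters. Best-matching-unit ties
break toward the smallest node index in row-major order, making training
and assignment fully deterministic under a fixed seed.

**Cohesion.** A cluster's cohesion R is the mean pairwise Pearson
correlation of member one-hot vectors, computed over the A/C/G/T
indicator columns (an N position contributes an all-zero block). On the
4-letter encoding, two reads agreeing at a fraction m/L of positions
correlate at (4m/L − 1)/3, so identical reads give R = 1 and fully
divergent reads R = −1/3; this is the scale on which the 0.95
subclustering threshold operates. Above 10,000 member pairs a seeded
uniform subsample of 10,000 distinct pairs is used. Singletons score 1 by
convention. Clusters with R < 0.95 are re-clustered once (no recursion)
on a 10 × 10 grid with the same round count; their subclusters replace
the parent.

**Representatives.** Each final cluster's representative is the member
maximizing Pearson correlation with the cluster's mean one-hot profile,
ties broken toward the smallest read index.

## Taxonomy assignment and frequency tables

Representatives are aligned against every template of a local species
reference with Smith–Waterman local alignment (match +1, mismatch −1,
affine gaps: −2 for a gap's first position, −1 per extension — a scoring
scheme chosen to mimic default nucleotide-search behaviour, and
configurable). The best score wins; ties break to the lexicographically
smallest species id. Clusters whose best alignment spans fewer than 200
columns (including gaps) are dropped from counting; no identity threshold
is applied beyond the length filter, which is a documented caveat of the
procedure. A species' per-sample count is the summed size of its
clusters, and frequencies divide by the total count of sequences in
*selected* (filter-passing) clusters of the sample, so rows sum to 1.

Note that with 200-nt reads the ≥ 200-column filter effectively demands a
full-length alignment: a representative whose terminal base is erroneous
can be trimmed by the local aligner and its cluster dropped. At the
default 0.5% substitution rate this affects on the order of 1% of
clusters and is absorbed by the renormalization.

## Community metrics

Simpson's index of diversity D = 1 − Σ pᵢ² (probability that two randomly
drawn sequences belong to different species), species richness
(frequency > 0; counts are integers upstream, so presence needs no
pseudo-threshold), and taxonomy rollups that sum frequencies within a
rank and conserve row totals. The group-specific species filter selects
species present in at least one target-group sample and absent from
every excluded-group sample, reporting a carrier histogram (species
carried by exactly k target donors). The BMI screen computes per-species
Pearson correlation of frequency with donor BMI across donors at one
timepoint (the screen is per-timepoint on frequencies; zero-variance
species have undefined R, reported as 0 and never flagged). The
per-donor eukaryote score sums a given species set's frequencies across
T0 and T3 samples of each donor; the default differential set is chosen
by a two-sided Welch test at p < 0.1 (configurable).

## Pathway scores

The pathway database is a species × pathway score table in [0, 1] with a
two-level hierarchy (H1: biosynthesis / degradation / energy / other; H2
subcategories) — the TSV contract any MACADAM-style export can satisfy;
live database access is out of scope. Per-sample pathway scores are
abundance-weighted sums, hence linear in frequencies; hierarchy rollups
sum member pathways and conserve totals. Species absent from the
database contribute zero and the covered frequency mass is logged.
Fasting-shift summaries run one-sided paired t-tests on donor-matched
category scores separately per group; the species change profile pairs
each species' mean frequency change (T3 − T0) with its summed
category score, sorted by change (ties toward smaller species id).

## Statistics

One-sided paired t (kinetics) and Welch's t (group comparisons, two-sided
by default since study conventions leave sidedness open) delegate to
scipy; one-sided directions must be declared per analysis. Zero-variance
differences are degenerate and raise rather than returning a fabricated
p-value; a mean-zero difference with spread gives t = 0, p = 0.5.

The Wilcoxon signed-rank test drops zero differences, ranks |d| with
midranks, and computes P(W⁺ ≥ w) exactly for n ≤ 25 by dynamic
programming over sign assignments (midranks doubled to stay integral);
above n = 25 a normal approximation with continuity and tie correction
is used. Tests verify the exact path against brute-force enumeration of
all 2ⁿ sign patterns and against scipy's exact method, and the
approximation against the exact path at n = 15 (within 0.01).

Per-population significance profiles report the three comparisons
(paired t RA T0→T1, paired t RA T0→T2, Welch RA vs MetS at T0), their
−log10 transforms, flags at α = 0.05 and the combined score = max of the
three p-values — a population must differ in *every* comparison to rank
well. Populations are ranked by ascending combined score. No
multiple-testing correction is applied by default (profiles present raw
−log10 p); a Benjamini–Hochberg helper is available. Donor pairs with a
missing timepoint are dropped per comparison, never imputed. Fractions
are converted to cells/nL by multiplying with the donor's measured
leukocyte blood count.

## Clinical scores

DAS28-ESR uses the standard published coefficients
(0.56, 0.28, 0.70, 0.014); SDAI is the plain sum with globals in cm and
CRP in mg/dL (standard convention). Category boundaries: DAS28 < 2.6
remission, ≤ 3.2 low, ≤ 5.1 moderate, above high; SDAI remission at
≤ 3.3. SDAI response uses strict percent-reduction cuts (> 85 major,
> 70 moderate, > 50 minor) on the raw scores, not on pre-rounded
percentages. The EULAR grid is standard (good: improvement > 1.2 and
attained ≤ 3.2; moderate: improvement > 1.2 at higher levels or > 0.6
with attained ≤ 5.1; otherwise none), with a stable-remission label
reserved for patients below 2.6 at both timepoints whose grid result
would be "none". Responses are computed per post-baseline timepoint and
the best across T1–T3 is reported alongside (ordered GR > MR > SR > NR);
the packaged cohort table's 60 printed per-timepoint labels and its
best-response tallies are all reproduced by this grid. Medians of
even-sized cohorts average the two central values. RF positivity is
strict at > 14 U/L (the assay reports 14 as a floor value) and ACPA
inclusive at ≥ 17 U/L; both thresholds are inferred from the assay
conventions visible in the data, not stated ones, and are configurable.

## Synthetic-data generator

The generator produces every pipeline input with known ground truth. Its
defaults encode the study conditions the package is tested under:

- **Reference**: 20 species, 200-nt templates, genera of 2 species drawn
  from independent random ancestors (cross-genus divergence ≈ 75%).
  The within-genus divergence parameter d is the *expected pairwise*
  divergence between same-genus templates: the per-species mutation
  count k solves E[pairwise mismatches] = 2k − (4/3)k²/L = d·L, valid
  for d ≤ 3/4. Default d = 0.2, which keeps the minimum pairwise
  divergence above 0.10 with margin. Bacterial genera cycle through
  Firmicutes, Bacteroidetes, Proteobacteria, Actinobacteria and
  Verrucomicrobia; a trailing ~25% block is fungal (eukaryote), giving
  ITS/18S compositions a smaller species pool (lower richness), as
  observed for eukaryotic colonizers.
- **Compositions**: donor-level Dirichlet baselines (concentration 2);
  T3 reweights T0 by per-phylum multipliers (defaults 0.6 for Firmicutes
  and Actinobacteria, 1.8 for Bacteroidetes and Verrucomicrobia, 1.4 for
  Proteobacteria) and renormalizes — the fasting "generalist shift".
  Rare RA-specific species are spiked into configured RA donors' T0
  samples at 5 × 10⁻⁴ (the below-10⁻³ regime) and nowhere else.
- **Reads**: exactly `depth` template copies (default 2000) with i.i.d.
  substitutions (default 0.5%) to one of the three other bases; the
  read → species map is stored as hidden truth, consumed only by tests.
  Substitution errors only: the clustering operates on fixed-length
  reads, so indels, chimeras, primer/barcode structure and quality-score
  models are deliberately not simulated. Passing recovery tests
  therefore show correctness of the clustering/assignment machinery
  under substitution noise, not robustness to indel-rich platforms.
- **Pathway DB**: uniform scores with an additive bias (+0.3 on
  biosynthesis, half on degradation/energy) for Bacteroidetes and
  Proteobacteria species, making the phylum-level metabolic shift
  recoverable.
- **Clinical & cytometry tables**: lognormal-noise components with
  multiplicative RA improvement across timepoints; population fraction
  tables (Dirichlet base, lognormal donor and sample noise, default 110
  populations) with one designated population carrying an RA baseline
  deficit (×0.5 vs control) plus a fasting increase — the non-classical
  monocyte pattern. Configuring the effect away yields exact null
  tables for calibration tests.

All generators are deterministic under a fixed seed, with child seeds
derived via `numpy` seed sequences.

## Problem sizes and numerical choices

The recovery experiments run the full 20 × 20 / 10,000-round SOM on
2000-read samples (about 10–15 s per sample); the test suite and the
acceptance script use two such samples, which is sufficient for the
per-sample error metrics they assert. Type-I calibration uses 10,000
simulated nulls at n = 20. Cohesion and correlation computations run in
float32 and are clipped to [−1, 1] to absorb accumulation error; BMU and
representative ties break deterministically as described; degenerate
statistical inputs raise typed errors rather than returning NaN.

## Known limitations

- No indel-aware distance, de-noising (error-model) step or chimera
  removal; reads shorter than the nominal length are discarded rather
  than aligned.
- The alignment stage is exhaustive against the provided reference —
  appropriate for curated references of hundreds of species, not a
  GenBank-scale search (no k-mer seeding).
- The alignment-length filter without an identity threshold can retain
  low-identity full-length hits; with curated references this is
  harmless, against noisy references an identity cut should be added.
- Cytometric population *discovery* (mixture-model clustering and
  meta-clustering of FCS events) is upstream of this package, which
  consumes population × sample count tables.
- The clinical module computes DAS28-ESR only (no CRP variant) and no
  Boolean remission, which needs per-component data.
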