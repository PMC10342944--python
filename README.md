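# microfast

Analysis toolkit for fasting-intervention microbiome/immunology studies in
rheumatoid arthritis (RA): self-organizing-map (SOM) clustering of amplicon
reads, alignment-based taxonomy assignment and species frequency tables,
community diversity metrics, frequency-weighted metabolic pathway scores,
cytometric population significance profiles, and DAS28/SDAI clinical
disease-activity scoring with EULAR/SDAI response classification.

It is written for studies that monitor RA patients (with a metabolic-syndrome
control group) across fasting timepoints T0 (baseline), T1 (early fasting),
T2 (end of fasting) and T3 (after breaking the fast), sequencing gut
microbiota with 16S/ITS/18S markers and profiling blood leukocytes by flow
cytometry. A synthetic-data module generates every input with known ground
truth so the whole pipeline is testable end to end.

## Core methods

**SOM read clustering.** Fixed-length reads (200 nt) are one-hot encoded over
A/C/G/T/N and clustered on a 20 × 20 SOM with 10,000 rounds of training. The
read-node distance is the soft Hamming distance
`d(read, node) = Σ_pos (1 − w[pos, base(read, pos)])`, which equals the integer
Hamming distance whenever the node profile is one-hot. Cluster cohesion is the
mean pairwise Pearson correlation *R* of member one-hot vectors; clusters with
R < 0.95 are re-clustered once on a 10 × 10 grid, and each final cluster's
representative (member closest to the cluster mean profile) is aligned locally
(+1/−1, gaps −2/−1) against a species reference. Clusters whose best alignment
spans < 200 columns are dropped; per-sample species frequencies are
selected-cluster sizes over the total selected count.

**Community and pathway metrics.** Simpson's index of diversity `D = 1 − Σ pᵢ²`,
species richness, taxonomy rollups, group-specific presence/absence filters,
BMI correlation screens, and MACADAM-style pathway scores
`PS(sample, pathway) = Σ_s freq(s) · score(s, pathway)` with two-level hierarchy
rollups (biosynthesis / degradation / energy ...).

**Statistics.** One-sided paired *t*-tests for kinetics, Welch tests for
RA vs MetS, Wilcoxon signed-rank (exact by enumeration up to n = 25) for joint
counts, and per-population significance profiles whose combined score is the
*weakest* of the three p-values (RA T0→T1, RA T0→T2, RA vs MetS at T0).

**Clinical scores.** `DAS28-ESR = 0.56√TJC28 + 0.28√SJC28 + 0.70 ln(ESR) +
0.014·GH` and `SDAI = TJC28 + SJC28 + PGA + EGA + CRP`, with the standard
activity categories, EULAR response grid and SDAI percent-reduction responses.
A transcription of the study cohort's clinical table ships with the package.

## Worked example

```python
>>> import microfast as mf
>>> summary = mf.cohort_summary(mf.load_table1())
>>> round(summary["median_delta_das28"], 2)
-1.23
>>> summary["n_improved"], summary["n_patients"]
(19, 20)
>>> summary["das28_remission"]
{'T0': 2, 'T1': 3, 'T2': 6, 'T3': 8}
>>> summary["eular_best_counts"]
{'MR': 8, 'GR': 8, 'NR': 3, 'SR': 1}
```

The median DAS28 dropped by 1.23 points between baseline and three days after
breaking the fast; 19 of the 20 RA patients improved, DAS28 remission rose
from two patients to eight, and the best EULAR response across post-baseline
timepoints was good for eight patients, moderate for eight, none for three,
with one patient in stable remission.

Clustering a simulated sample and recovering its composition:

```python
>>> from microfast import synthetic, som, taxonomy
>>> ref = synthetic.generate_reference(20, 200, 0.2, seed=7)
>>> design = synthetic.generate_cohort(n_ra=1, n_mets=1, seed=1, timepoints=("T0", "T3"))
>>> comp = synthetic.generate_composition(design, ref, seed=2)
>>> reads = synthetic.simulate_reads(comp.frequencies.iloc[0], ref, depth=2000,
...                                  substitution_rate=0.005, seed=3)
>>> clusterer = som.AmpliconClusterer(random_state=11).fit(reads)
>>> assigned = taxonomy.assign_clusters(clusterer.clusters_, clusterer.encoded_, ref)
>>> table = taxonomy.build_frequency_table({"s": taxonomy.species_counts(assigned)})
>>> (table.frequencies.iloc[0].reindex(comp.frequencies.columns).fillna(0)
...  - comp.frequencies.iloc[0]).abs().mean() < 0.02
True
```

The same stages are available from the shell:

```bash
microfast simulate --seed 0 --out simulated
microfast cluster --reads simulated/RA_01.T0.16S.fastq --grid 20x20 --seed 0 --out clusters.tsv
microfast assign --clusters clusters.tsv --reference simulated/reference.fasta \
    --taxonomy simulated/taxonomy.tsv --out frequencies.tsv
microfast clinical --summary
microfast run --seed 0 --out pipeline_out   # full end-to-end pipeline
```

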