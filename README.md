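# rehonorm

Normative modeling of regional homogeneity (ReHo) and deviation-based
patient subtyping for multi-site resting-state fMRI cohorts.

## The problem

Case–control comparisons of rs-fMRI features average over patients and miss
the heterogeneity of psychiatric disorders such as major depressive
disorder (MDD). An alternative is *normative modeling*: fit a reference
model of a brain feature as a function of age and sex in healthy controls
(HC), the way growth charts reference a child's height, then score each
patient by how far they deviate from the norm. Clustering those deviation
maps can reveal patient subtypes with distinct neurophysiology.

`rehonorm` implements this workflow end to end for regional homogeneity —
Kendall's coefficient of concordance (KCC, W) of each voxel's time series
with its neighbors, averaged within the 246 regions of a whole-brain
parcellation:

1. **ReHo extraction** — voxel-wise W over 7/19/27-voxel neighborhoods
   (midranks for ties, no tie-correction factor) reduced to 246 regional
   means through a label atlas.
2. **ComBat harmonization** — parametric empirical-Bayes removal of
   additive and multiplicative site effects per site × region, preserving
   age and sex effects.
3. **Normative model** — one Gaussian-process regression per region,
   ReHo ~ GP(age, sex), kernel = squared-exponential + linear + white
   noise, hyperparameters by marginal likelihood. 10-fold cross-validation
   reports SMSE and MSLL; each subject gets a Z-deviation per region,

   Z = (y − μ) / √(σ²_f + σ²_n),

   with |Z| > 2.6 (two-sided p < 0.005) flagged as an extreme deviation.
4. **Deviation statistics** — per-subject deviation indices and extreme
   counts, per-region overlap maps, prevalence summaries, and the usual
   comparison statistics (Welch t, ANOVA/ANCOVA with partial η², Cohen's
   d, Cramér's V, Pearson r, Benjamini–Hochberg FDR).
5. **Subtyping** — Euclidean k-means on the patient Z-maps, with k chosen
   by majority vote over eleven cluster-validity indices; network-level
   summaries over 8 canonical networks (FPCN, VAN, DMN, LN, DAN, SMN, VN,
   SUB).
6. **Stability validation** — per-site clustering, leave-one-site-out
   reclustering, subgroup reruns (sex, median-age split, clinical
   subgroups), compared with the primary labels via aligned label-overlap
   rates and the adjusted Rand index.

A synthetic cohort generator produces multi-site HC/MDD data with all the
structure the analysis assumes — nonlinear age trajectories with sex
offsets, ComBat-style site effects, and two planted MDD subtypes with
opposing network-level deviation patterns plus correlated clinical
variables — so every stage is testable without any imaging download. Real
regional-ReHo tables (TSV + phenotype TSV) are ingested through
`rehonorm.pipeline.load_feature_table`.

## Worked example

Generate patient deviation maps with the default planted subtype structure
(two subtypes, 36/64 mixing, network-level |d| between 0.40 and 1.81 with
opposing signs in transmodal vs unimodal networks), select k, cluster, and
validate:

```python
from rehonorm import subtyping
from rehonorm.synthetic import (
    CohortConfig, generate_region_specs, generate_mdd_deviations,
)

regions = generate_region_specs(seed=1)
config = CohortConfig(n_mdd=600, n_sites=6, seed=7)
cohort, z = generate_mdd_deviations(config, regions)

report = subtyping.select_k(z, k_range=(2, 8), seed=0)
print("selected k:", report.winning_k, "votes:", report.tally)

result = subtyping.cluster_subjects(z, report.winning_k, seed=0)
print("cluster sizes:", result.labels.value_counts().to_dict())

truth = cohort.set_index("subject_id")["true_subtype"]
print("ARI vs planted subtypes:",
      round(subtyping.adjusted_rand(truth.to_numpy(), result.labels.to_numpy()), 3))

sites = cohort.set_index("subject_id")["site_id"]
loso = subtyping.leave_one_site_out(z, sites, report.winning_k, seed=0,
                                    primary=result)
print("leave-one-site-out overlap: min %.1f%%, mean %.1f%%"
      % (loso.min_overlap, loso.mean_overlap))
```

This prints:

```
selected k: 2 votes: {2: 7, 8: 3, 6: 1}
cluster sizes: {1: 376, 2: 224}
ARI vs planted subtypes: 0.889
leave-one-site-out overlap: min 99.8%, mean 99.9%
```

Seven of the eleven validity indices vote for two clusters; the recovered
minority share (224/600 ≈ 37%) sits near the planted 36%; the clustering
agrees strongly with the planted subtypes (ARI 0.89); and removing any one
acquisition site changes at most 0.2% of the labels.

The full pipeline (generate → harmonize → fit normative models →
deviations → statistics → subtype → validate) runs from one config:

```bash
rehonorm run --out my_run --seed 0          # or: --config pipeline.yaml
```

outputs land under `my_run/` as TSV/JSON with a `manifest.json` recording
the config, per-stage seeds, wall-clock, and output checksums. Individual
stages are exposed as subcommands (`simulate`, `reho`, `harmonize`,
`fit-normative`, `deviations`, `devstats`, `subtype`, `validate`).

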