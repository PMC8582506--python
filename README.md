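# ffpe16s

Paired FF/FFPE 16S microbiome comparability analysis.

Formalin-fixed, paraffin-embedded (FFPE) tissue is the most widely
archived clinical material, but formalin fixation degrades DNA and blocks
accumulate reagent/environmental bacteria, so whether an FFPE microbiome
profile still reflects the matched fresh-frozen (FF) tissue is an open
question for every retrospective study. `ffpe16s` is a toolkit for
researchers who face that question with paired 16S rRNA amplicon data: it
implements negative-control decontamination, diversity and ordination
statistics, discriminant-taxon detection, a dominance-based comparability
index for FFPE samples, and concordance analysis between 16S sequencing
and RNA in situ hybridisation (RNA-ISH) presence calls. A synthetic
paired-cohort generator with planted contamination ground truth makes the
whole pipeline testable end to end without any sequencing download.

## The statistics at the core

Given paired samples and a no-template control (NTC), the pipeline:

1. filters eukaryotic ASVs, subtracts every NTC-positive ASV identity,
   and removes cohort-wide singletons;
2. computes Shannon diversity H = −Σ pᵢ ln pᵢ on rarefied counts, and
   Bray–Curtis, binary Jaccard and Jensen–Shannon dissimilarities
   d(x, y) ∈ [0, 1] on relative abundances, with PCoA ordination and Ward
   clustering;
3. tests preservation effects with single-factor PERMANOVA,
   F = (SS_B/(a−1))/(SS_W/(N−a)) with a permutation p-value, and detects
   discriminant taxa with a two-class LEfSe (Kruskal–Wallis gate at
   α = 0.05, bootstrapped LDA effect size, score > 3);
4. scores each pair's comparability: dominance D = relative abundance in
   the FFPE sample of the two most abundant orders of its matched FF
   sample, contaminant prevalence C = FFPE mass of typical contaminant
   taxa, with the pair called **high** iff D > 50% and C ≤ 25%, and
   Spearman correlations (BH-adjusted) of D against the pair
   dissimilarities;
5. thresholds RNA-ISH (≥ 100 counts) and 16S (≥ 10 reads) into presence
   calls and summarises cross-platform concordance as "k of n
   reference-positive pairs".

## Worked example

Simulate a default cohort (10 pairs, contamination gradient 0.05–0.8, one
NTC), run the cascade, and score comparability:

```python
import ffpe16s as f

cohort = f.simulate_cohort(f.SimulationConfig(seed=1))
table, report = f.run_preprocessing(cohort.table, cohort.taxonomy, "NTC")
meta = f.SampleMetadata(cohort.metadata.frame.drop(index=["NTC"]))
records = f.compute_pair_qc(table, cohort.taxonomy.subset(table.asv_ids),
                            meta, seed=1)
print(f.records_to_frame(records)[["dominance_ffpe",
      "contaminant_prevalence_ffpe", "comparability"]].round(2))
print(f.dominance_dissimilarity_correlation(records).round(4))
```

```
            dominance_ffpe  contaminant_prevalence_ffpe comparability
patient_id
P01                  86.84                         2.60          high
P02                  81.23                         6.76          high
P03                  76.68                        11.57          high
P04                  73.31                        16.98          high
P05                  66.61                        22.40          high
P06                  59.91                        28.47           low
P07                  56.94                        36.57           low
P08                  45.62                        45.16           low
P09                  41.67                        53.33           low
P10                  29.85                        65.41           low

                   rho  p_value  p_adjusted
metric
bray_curtis    -1.0000      0.0         0.0
jaccard        -0.9636      0.0         0.0
jensen_shannon -1.0000      0.0         0.0
```

Dominance falls and contaminant prevalence rises monotonically along the
planted contamination gradient, the high/low calls flip where the planted
fraction crosses the cutoffs, and dominance correlates strongly and
negatively with all three pair dissimilarities — the behaviour the
comparability index is designed to exhibit. On the same cohort, PERMANOVA
on Bray–Curtis distances attributes r² ≈ 0.42 of community variance to
preservation (p = 0.001, 999 permutations).

The same pipeline is scriptable from a shell:

```
ffpe16s simulate --n-pairs 10 --seed 1 --outdir cohort/
ffpe16s preprocess cohort/ --control-sample NTC --outdir filtered/
ffpe16s qc-index filtered/ --outdir qc/
```

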