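# crcmicro

Community-ecology analysis and machine-learning staging of the tumor
microbiome in colorectal cancer (CRC), working from 16S amplicon ASV tables.

Colorectal tumors carry an in-situ bacterial community that shifts as the
disease progresses from benign polyps (BP) through the four TNM tumor stages
(T1–T4). `crcmicro` implements the full analysis a microbial-ecology study of
that progression needs, as a tested, reusable library plus a thin CLI:

* **Preprocessing** — taxonomy-based exclusion (Mitochondria, Chloroplast,
  Archaea, Eukaryota), a ≥3-sample prevalence filter, rarefaction to even
  depth (default 14,221 reads, without replacement), relative-abundance
  conversion, and collapsing to any rank from phylum to genus.
* **Community statistics** — Shannon diversity; Bray–Curtis dissimilarity
  `d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)`; perMANOVA (adonis2-style marginal tests
  with free label permutation, plus exact enumeration for small n); CAP
  ordination (PCoA → LDA with leave-one-out axis selection and optional
  conditioning); community stability via the average variation degree
  AVDⱼ = meanᵢ |xᵢⱼ − μᵢ| / σᵢ (lower = more stable); UpSet-style
  group-presence intersection counts; SPEC-OCCU specialist screening
  (specificity ≥ 0.5 and occupancy ≥ 0.5 among each group's 500 most
  abundant ASVs); Kruskal–Wallis differential abundance with BH correction.
* **Driver-taxon detection** — per-group Spearman co-occurrence networks
  (|ρ| ≥ 0.6, BH-adjusted p ≤ 0.05), common sub-network extraction, a
  neighbor-shift (NESH-style) rewiring score
  `(1 − |A∩B|/|A∪B|) + |B∖A|/|A∪B|` ∈ [0,2] for control/case neighborhoods
  A/B, and a driver flag = top-decile NESH **and** increased betweenness
  from control to case.
* **Stage diagnosis** — a two-stage random-forest model: (1) regress host
  age on relative abundances over control samples, rank features, pick the
  minimal age-discriminatory set from a 10-fold CV curve and exclude it;
  (2) classify BP/T1–T4 on the remaining features, keep the top 15, and
  diagnose with a 50% vote cutoff. Reports are 5×5 observed-by-diagnosed
  confusion matrices with overall/per-class accuracy, a cancer-diagnosed-
  as-BP false-negative audit, and age/gender bias tests.
* **Synthetic cohorts** — because the motivating study's sequencing data are
  not publicly deposited, a first-class generator produces cohorts with the
  same design (95 samples: 45 BP, 9/13/22/6 across T1–T4; ages 21–89;
  70 male / 25 female; ~81,710 ± 47,466 reads) and *planted, recorded*
  age-associated, stage-discriminatory, and network-rewired taxa, so every
  inference step can be tested as a parameter-recovery problem.

## Worked example

```python
import dataclasses
from crcmicro import prep, ecology, networks, classify
from crcmicro.simulate import SimulationConfig, generate_cohort

cfg = dataclasses.replace(SimulationConfig(), n_taxa=300, rarefy_depth=8000,
                          depth_mean=24000, depth_sd=6000, seed=0)
counts, meta, tax, truth = generate_cohort(cfg)
rarefied = prep.rarefy(prep.filter_taxa(counts, tax), depth=8000, seed=0)
rel = prep.to_relative(rarefied)

dm = ecology.bray_curtis(rel)
res = ecology.permanova(dm, meta, ["group", "age", "gender"], n_perm=999, seed=0)
print(res.table.round(3))
```

```
          df     ss     r2      f      p
term
group      4  0.885  0.088  2.345  0.001
age        1  0.587  0.058  6.218  0.001
gender     1  0.095  0.009  1.006  0.430
residual  88  8.300  0.827    NaN    NaN
```

Disease stage explains 8.8% of community variation and host age 5.8% (both
significant at p = 0.001), while gender explains nothing — the generator
plants stage and age effects but no gender effect, and the test recovers
exactly that structure.

Staging on the same cohort:

```python
reports, best = classify.rank_sweep(rarefied, tax, meta, seed=0,
                                    ranks=("phylum", "asv"), top_k=15,
                                    n_estimators=200)
rep = reports[best]["combined"]
print(best, round(rep.overall_accuracy, 3), rep.false_negatives)
```

```
asv 0.716 22
```

ASV-level features win the sweep, as expected when stage effects are
planted at ASV resolution and diluted by collapsing. Overall accuracy at
this reduced simulation size (300 taxa, depth 8,000) is 71.6%; the
false-negative count reflects how hard the small tumor stages (T1 n = 9,
T4 n = 6) are at these effect sizes.

The CLI mirrors the library: `crcmicro simulate|preprocess|diversity|drivers|
stage-model|run-all`, each writing plain TSV/JSON outputs.

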