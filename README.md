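# tripathotype

Analysis pipeline for **histology-anchored stratification of early
rheumatoid arthritis synovium**, re-implemented as a tested, reusable
Python package and exercised end-to-end on synthetic cohorts with
planted ground truth.

Treatment-naive RA synovium falls into three histological *pathotypes*
by semiquantitative immunostaining: **lympho-myeloid** (L; CD20⁺ B-cell
aggregates), **diffuse-myeloid** (M; sublining CD68⁺ macrophage rich,
B-cell poor) and **pauci-immune fibroid** (F; sparse immune
infiltrate). The pipeline connects these pathotypes to bulk RNA-seq of
synovium and blood through five computational stages:

1. **Pathotype classification** from ordinal IHC scores (CD3, CD20,
   CD68L/SL, CD138 on 0–4; aggregate grade 0–3), precedence L > M > F,
   with `ungraded` for rule-gap combinations.
2. **Cell-specific gene modules** from a primary-tissue reference
   expression atlas: per-gene cross-tissue Z scoring, tissue ranks, and
   a specificity score (number of tissues with Z > 3); a gene is a
   tissue marker iff rank ≤ 3, Z > 5 and specificity < 10.
3. **Eigengene module scores**: the first right-singular vector of the
   row-centered module submatrix, one score per sample, sign-anchored to
   the module-mean profile; compared across pathotypes by one-way ANOVA
   with Bonferroni post-tests and against clinical variables by tertile
   tables and linear regression.
4. **Three-group differential expression** on counts: median-of-ratios
   size factors, per-gene negative-binomial GLM likelihood-ratio test of
   pathotype (optionally with batch/sex covariates) plus pairwise tests,
   Benjamini–Hochberg FDR, and six-way color classes (up in one group →
   blue/red/green; up in two → purple/yellow/cyan; else gray).
5. **Polar "three-way volcano" projection** of per-gene group summaries
   (L, M, F), exactly as RGB maps to hue/saturation:

   ```
   x = √3/2 · (M − F),   y = L − (M + F)/2
   θ = atan2(y, x),      r = √(x² + y²),   z = −log₁₀ p(LRT)
   ```

   so L, M, F point to 90°, 330°, 210°. Module–trait Spearman
   correlations with per-family FDR, synovium/blood concordance labels,
   hypergeometric cell-type annotation, Welch-t group comparisons, and
   a 6-month pathotype-shift vs ΔDAS28 analysis complete the chain.

Because the real cohort (ArrayExpress E-MTAB-6141) is not required, the
`synthetic` module generates every input with planted truth: atlas
markers, six classes of differential genes, per-sample module
activities, rule-consistent histology, Spearman-calibrated clinical
traits, and a follow-up with a planted shift–response coupling.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
synthetic cohorts (65 synovium-like and 67 blood-like samples, 2,000
genes) and write their tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_classify_histology.py
...
python analysis/08_followup_response.py
```

Selected output (what the scripts actually print):

```
pathotype calls: {'lymphoid': 24, 'ungraded': 3, 'myeloid': 19, 'fibroid': 19}
agreement with planted labels: 65/65

marker sensitivity: 100.0% of 1350 planted markers
broad-gene exclusion: 100.0% of 100 decoys kept out

synovium: 321 significant genes (planted 300); colors {'gray': 1679,
  'blue': 59, 'yellow': 50, 'green': 55, 'cyan': 52, 'purple': 50, 'red': 55}
blood: 3 significant genes (planted 8); colors {'gray': 1997, 'blue': 3}

single-class planted genes inside their 120-deg sector: 100.0%
pathotype shift vs ΔDAS28-ESR: Pearson r = 0.48 (p = 7.5e-05, n = 62 graded pairs)
```

Reading this: the classifier reproduces every planted pathotype; the
printed atlas criteria recover all planted markers while excluding all
broadly expressed decoys; the DE stage finds essentially the planted 300
synovium genes with their planted colors while the low-effect blood
cohort yields only a handful (mirroring the study's stark
synovium/blood asymmetry); projected single-class genes land in their
group's 120° sector; and biopsies that shifted to a less inflammatory
pathotype show larger DAS28 improvement, as planted.

A `tripathotype` console command exposes each stage
(`simulate`, `classify`, `derive-modules`, `score`, `de`, `project`,
`associate`, `annotate`, `run-all`); `run-all --config config.yaml`
executes the full pipeline and writes a manifest with input/output
hashes so reruns are byte-identical.

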