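# Methods

`clipmeta` implements a meta-analysis framework for identifying cancer cell
line-specific (CCS) genes from heterogeneous multi-omics panels profiled at
multiple research sites, and for mining the resulting gene signatures for
genetic interactions and synthetic-lethal (SL) partners of mutated driver
genes. This note records the model, its assumptions, the tunable parameters,
what the bundled simulator does and does not emulate, and the numerical
choices made where the design was open.

## The model

### Evidence scores

For a **continuous** modality (methylation METH, gene expression GEXP,
protein expression PEXP, phospho-protein PHOS, gene dependency FUNC, target
addiction TAS), the evidence that gene *G* is specific to cell line *j* in
dataset *D* is the **outlier evidence score**

    OES_{G,D,j} = (X_{G,j} − mean_i X_{G,i}) / SD_i X_{G,i},

a z-score of the line against all lines in that dataset (sample SD, n−1).
Genes observed in fewer than 3 lines or with zero dispersion are excluded.
For a **binary** modality (point mutation MUT, copy-number gain/loss
CNV_GAIN/CNV_LOSS), the evidence is the **proportion score** PS = F/N, the
alteration frequency in the panel (missing entries leave both F and N).

### Rank-product integration

Per cell line and modality, OES profiles from every covering dataset are
reduced to normalized rank ratios (rank/n, average ranks for ties; rank 1 =
most extreme in the feature's direction) and combined as the geometric mean
over covering datasets — the one-class rank product. Significance is the
**pfp** (proportion of false positives): gene labels are permuted
independently within each dataset, the rank product is recomputed, and

    pfp_g = E_g / rank_g,    E_g = E_perm[# null genes with rp ≤ rp_g],

an FDR-like quantity. Raw pfp values are monotonized by a cumulative
maximum along increasing rank product so that any pfp threshold selects a
prefix of the rp-sorted gene list; raw values are retained alongside.
Genes covered by a single dataset get rp and pfp at k = 1, but there the
permutation null equals the observed multiset and pfp ≡ 1 — which is why
the single-study fallback below exists.

### CCS and rCCS calls

Thirteen modality features are assessed per cell line: METH, GEXP, PEXP and
PHOS in both directions; FUNC down only (a low dependency score means the
line needs the gene); TAS up only (high addiction); CNV gain; CNV loss; MUT.
These map onto eight modality types (gain and loss share the CNV type).

* Continuous features, ≥2 covering datasets: genes with pfp < 0.10 are CCS
  (pfp < 0.25 for FUNC, reflecting the lower cross-site consistency of
  dependency screens).
* Continuous features, 1 covering dataset: fixed top-k fallback — 100 genes
  (200 for FUNC, 10 for the ~200-protein phospho panels), per direction.
* Binary features: an alteration carried by the line and observed in ≤10%
  of lines in at least one covering dataset (an "all datasets" variant is
  available via `ClipConfig.binary_rule`).

A gene with CCS evidence in **two or more modality types** in the same line
is a robust CCS (**rCCS**) gene; CNV gain + loss alone never qualify.

### Target addiction scores

Drug response lives in compound space; the TAS projection moves it to gene
space using drug polypharmacology: TAS_t is the mean drug-sensitivity score
(DSS) over all measured compounds that potently target protein *t*, primary
and off-targets pooled and unweighted. Compounds missing a response in a
line are dropped from that line's mean.

### Concordance

Cross-site reproducibility is measured between identical cell lines on the
genes shared by a dataset pair: Spearman's correlation for continuous
profiles, Matthews correlation coefficient for binary ones (p via the
χ² identity n·MCC²). Records with fewer than 10 shared genes or p ≥ 0.05
are flagged excluded. A seeded sample of non-identical line pairs gives the
baseline; the identical/baseline mean ratio with a Wilcoxon rank-sum p
summarizes how much signal is line-specific.

### Genetic interactions and synthetic lethality

For a driver mutated in ≥5 cell lines of the epithelial subset (all lines
except bone, skin, nervous-system and hematopoietic lineages), a two-sided
Fisher's exact test compares how often a partner gene is rCCS in mutant vs
wild-type lines. A significant pair is a candidate SL interaction when the
partner's rCCS evidence includes the dependency modality in at least one
mutant line (selective essentiality). The paralog benchmark tests both
directions within each paralog group (driver mutated in ≥10 epithelial
lines), in three settings: all modalities, FUNC-compulsory (the SL setting),
and FUNC-excluded. The single-dataset comparator replaces the rCCS logic
with a plain two-sample t-test on dependency scores between mutant and
wild-type lines — a deliberate simplification of a moderated
(empirical-Bayes) linear fit, which differs appreciably only at very small
panels. BH-adjusted p values are reported alongside raw ones in scans; the
stated thresholds apply to raw p.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `pfp_default` | 0.10 | CCS cutoff for METH/GEXP/PEXP/PHOS/TAS |
| `pfp_func` | 0.25 | relaxed cutoff for dependency screens |
| `ps_cutoff` | 0.10 | binary rarity rule (inclusive) |
| `fallback_top_continuous/func/phos` | 100 / 200 / 10 | single-study top-k |
| `n_perm` | 100 | permutations for pfp |
| CNV thresholds | ±1 BROAD; ±0.5 GDSC/SANGER/gCSI/OHSU; ±0.4 UHN/NCI60 | site-specific calls |
| FATHMM cutoff | −0.75 (inclusive) | deleterious-variant rule |
| promoter window | 200–1,500 bp upstream of TSS, inclusive | CpG averaging |
| CpG QC | missing rate > 5% or detection P > 0.05 removed (strict >) | |
| GI filters | ≥5 mutant lines (driver scan), ≥10 (paralogs) | power filters |
| comparator z | \|z\| > 1.66, strict | METH-only baseline |

Inclusive vs strict comparators follow the printed rules exactly (e.g.
PS = 0.10 qualifies; a CpG at exactly 5% missingness survives QC).

## The synthetic world

`synthdata.generate` emulates the structure of real cross-laboratory panels:
three sites (full, 80% and 60% panel coverage) measuring ~9 modalities on
2,000 genes × 120 cell lines. Per continuous modality a site's matrix is
`√ρ·Z + √(1−ρ)·E_site`, so the configured reliability ρ *is* the expected
cross-site correlation of identical lines; defaults follow the qualitative
ordering seen across laboratories (GEXP 0.90 high … FUNC 0.30 low). Binary
alterations are Bernoulli draws (background mutation frequency 3%, with a
handful of common genes at 30%; CNV events 2%) observed per site with
probability ρ. An optional `gene_effect_sd` adds shared per-gene baseline
levels: it leaves every CLIP statistic untouched (OES centers genes) but
lifts the correlation of non-identical lines the way shared transcriptional
programs do in real data; it defaults to 0 so the ρ-calibration property
holds exactly.

Planted truth:

* **Drivers** — fixed offsets in OES units added consistently at every
  covering site. Default effect 5 was chosen a priori: with a driver
  specific to a fraction p of lines, the realized z-score is bounded by
  √((1−p)/p) whatever the offset, and 5 puts a low-prevalence driver
  comfortably past the panel's extreme-value background.
* **SL pairs** — a driver mutated in 14 lines (~12% prevalence, matching a
  PTEN-like driver) whose partner loses 6 SD of dependency score and 5 SD
  of expression in mutant lines. The shifts come from the same bound: at
  12% prevalence the achievable partner z-score saturates near 2.7, so the
  planted shifts must be large for per-line outlier calls to clear pfp —
  consistent with how strongly true SL dependencies separate in genome-wide
  screens (essential-gene effects are many assay SDs wide).

The **recovery scenario** (`recovery_config`) used by the driver-recovery
test raises every reliability to ≥0.7 and uses full coverage, and plants
each driver across a subtype-sized group (10% of the panel, the ERBB2/HER2
pattern). Two facts make this the right test bed: recovery is only a fair
demand of the method when the planted modalities are reliable, and
panel-wide z-scoring gives null
genes non-trivial chance rCCS frequencies (a gene whose sample SD is
deflated by chance is a mild outlier in many lines at once), so frequency
ranking is only a meaningful benchmark for drivers that recur across a
group of lines — which is exactly what the method's frequency benchmark is
for.

What the simulator does **not** emulate: real genome coordinates or linkage,
tissue-specific expression programs, beta-distributed methylation values
(all continuous modalities are Gaussian), platform-specific batch effects
beyond the site-noise term, and clonal divergence of cell lines between
laboratories. A green recovery test therefore establishes that the
statistical machinery behaves as designed under the stated noise model, not
that it would reach the same operating point on any particular real panel.

## Numerical choices

* **Ties** — average ranks throughout (ranking, Spearman, quantile
  normalization). Quantile normalization places tied entries at the
  interpolated reference value of their average rank; with ties this can
  collapse a column's value multiset, so strict idempotence holds only for
  tie-free columns (the tie-free case is tested; the tie behaviour follows
  the standard limma-style scheme).
* **pfp monotonization** — cumulative maximum along increasing rank
  product. Conservative: a gene is never reported more significant than a
  gene with a smaller rank product.
* **Seeds** — a single run seed; each (cell line, feature) call derives a
  deterministic child stream via CRC32, so results are independent of the
  order in which lines are processed and bit-reproducible.
* **Fallback tie-break** — equal OES ranks resolved by gene identifier for
  determinism.
* **Degenerate inputs** — all-missing columns are errors in quantile
  normalization; zero-dispersion genes are excluded from OES; baseline mean
  ≤ 0 makes the concordance fold-ratio undefined (reported as NaN); a
  paralog benchmark with zero tested groups reports an absent proportion.
* **Missing data** — skipped, never imputed: per-line means (TAS,
  phospho/CpG averaging), per-gene moments (OES), and pairwise-complete
  profiles (concordance).

## Known limitations

* The permutation pfp is exact only in the limit of permutations; at the
  default n_perm = 100 the resolution of small pfp values is ~1/(100·rank).
* The OR-rule for binary CCS across datasets ("rare in any one dataset")
  is the literal reading of the rule; the stricter AND-rule is available
  but not the default.
* The SL essentiality flag requires dependency evidence in at least one
  mutant rCCS line; requiring it in all such lines would be stricter.
* The two-sample t comparator assumes equal variances; with <10 lines per
  group a moderated fit would be preferable.
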