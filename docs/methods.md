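# Methods note

This note records the statistical model the package implements, the
default parameter values and why they were chosen, the scope of the
synthetic generator, the numerical conventions, and known limitations.

## 1. Signature model

The classifier operates on **linear-scale** expression. Log2 input
(`ExpressionMatrix(scale="log2")`) is exponentiated exactly once before
scoring; this matters because the mean-centered normalization and the
ratios are not invariant under log transformation.

For marker $i$ and sample $\alpha$:

- Mean-centered normalization:
  $\tilde u_{i\alpha} = 100\, u_{i\alpha} / \sum_\beta u_{i\beta}$, so
  each marker row sums to 100 across the cohort. Missing panel genes,
  non-positive values, and zero row totals are errors, not silent
  imputation.
- Ratios: $r_{ij\alpha} = \tilde u_{i\alpha}/\tilde d_{j\alpha}$ for all
  (up, down) pairs — 60 per sample for the default 10 × 6 panel, emitted
  in up-major order.
- Score: the median $\tilde m_\alpha$ of the ratios. Call: MYC-high if
  $\tilde m_\alpha > 1$, MYC-low if $\tilde m_\alpha < 1$; the exact
  boundary $\tilde m_\alpha = 1$ is called MYC-low with
  `boundary_flag=True` rather than invented precision.

Properties the tests enforce: per-gene scale invariance (multiplying any
marker row by a constant leaves all scores unchanged — the platform-
robustness property); cohort dependence (scores are relative to the
cohort used for normalization, deliberately *not* invariant to adding or
removing samples); panel-swap reciprocity (exchanging up and down panels
maps $\tilde m \to 1/\tilde m$).

qPCR input enters through ΔΔCt quantification,
$\mathrm{RQ} = 2^{-[(Ct_t - Ct_{ref}) - (Ct_{t,cal} - Ct_{ref,cal})]}$,
with 28S rRNA (`RNA28S`) as the reference gene and the first sample as
calibrator. By per-gene scale invariance the classifier is unaffected by
the calibrator choice.

## 2. De-novo stratification and marker ranking

`hclust_two_groups` clusters samples by complete-linkage hierarchical
clustering on Euclidean distance over log2 values (scipy
`linkage`/`fcluster`, two clusters); the cluster with the higher mean
panel expression is labeled MYC-high. scipy's deterministic
nearest-neighbor-chain agglomeration supplies the tie-breaking rule; a
brute-force agglomeration oracle in the tests confirms the merge
sequence on small inputs. `ttest_rank` ranks genes by Welch's t (or
Mann–Whitney), flagging zero-variance genes (p set to 1, ranked last)
rather than producing NaNs; `bh_fdr` is the Benjamini–Hochberg step-up
(statsmodels `fdr_bh`, cross-checked against the closed form).
`select_marker_panel` takes the top 10 up-regulated genes *restricted to
the MYC-target block* and the top 6 down-regulated genes from the whole
matrix.

Because the generator gives every MYC-target gene the same effect size
(section 4), the identity of the learned top-10 up genes is exchangeable
noise within the target block; tests therefore assert exact recovery of
the 6-gene down panel and containment of the up panel in the target
block, not an exact up-gene list.

## 3. Enrichment (from scratch)

Weighted Kolmogorov–Smirnov enrichment score with weight exponent
$p = 1$: genes ranked by a vectorized Welch-t metric; hit increments
$|m_g|^p / \sum_{hits} |m|^p$, miss decrements $1/(N - k)$; ES is the
running-sum extremum. Significance by phenotype permutation: labels are
permuted, the metric is recomputed, and ES for all sets is evaluated in
batch via cumulative sums over membership matrices. NES divides ES by the
mean of same-sign permutation ES values; the p-value is the add-one
same-sign permutation p; FDR pools NES values across sets
(positive and negative handled separately). Defaults: 1,000
permutations, set sizes 15–500 after intersecting each set with the
measured genes (intersect first, then size-filter). Tests use smaller
gene universes and 100–250 permutations to keep the suite fast; the
defaults are the analysis-scale values.

## 4. Synthetic cohort generator

Scope: the generator reproduces the *statistical structure* of the study
— it is a parameter-recovery harness, not a biological simulator.

- Labels: exact quota, `round(frac_high * n)` MYC-high (17 of 55 at the
  defaults), random placement.
- Expression: per-gene baseline log2 level ~ N(7, 1.5²) (an RMA-like
  range), linear value $2^{(\mathrm{base} + \Delta \cdot \mathbb{1} +
  \varepsilon)}$ with $\varepsilon \sim N(0, 0.5^2)$. A 239-gene
  MYC-target block (the 10 up-markers plus `MYCT0001..MYCT0229`) gets
  $\Delta = 2$ (log2 fold change) in MYC-high samples; the 6 down-markers
  get $\Delta = 2$ in MYC-low samples; background genes (default 1,000)
  get no group effect. The shared $\Delta$ across the target block is a
  deliberate simplification; its consequence for panel learning is noted
  in section 2.
- Survival: exponential with rate $\ln 2 / \mathrm{median}$, medians 9.2
  (high) and 18.8 (low) months. Censoring: each record is independently
  selected for censoring with probability `censor_rate` (default 0.25);
  a selected record is censored at $U(0, \min(T, 3 \cdot \mathrm{median}))$,
  so `censor_rate=1` yields an all-censored cohort and `censor_rate=0`
  yields none. Because censoring is guaranteed for selected records,
  it is informative, and KM medians on censored synthetic cohorts are
  biased upward; recovery checks therefore use `censor_rate=0`.
- Chemograms: 4 cell lines per stratum, 4PL with IC50 2.3 μM (high) /
  39.22 μM (low), Hill 1, bottom 0, top 100; viability noise SD 5
  percentage points (0 for noiseless recovery). Dose ladder: 0 plus 9
  log-spaced doses from 0.1 to 30 μM (spacing is a package choice; only
  the 10-dose 0–30 μM range is fixed by the study design). The low-group
  IC50 lies beyond the maximum dose, which is why its recovery requires
  the constrained fit.
- Histology: Ki67 (0–4) means 2.88 / 2.06, differentiation (0–2) means
  0.77 / 1.82, clipped to range. The SDs are not published; defaults
  (ki67_sd = 1.0, diff_sd = 0.6) were back-derived from the published
  SEMs (e.g. $0.25\sqrt{17} \approx 1.03$) and chosen before any test
  was run.
- qPCR: Ct = ct0 − log2(linear expression) + noise, ct0 = 35, reference
  Ct = 12 (an abundant rRNA level), Ct noise SD 0.15 cycles — typical
  assay magnitudes, not published values; the classifier is invariant to
  ct0 and the reference level.
- Randomness: a single `seed` feeds `numpy.random.SeedSequence`, which
  spawns independent sub-streams per generator, so adding a generator
  never perturbs the others and identical configs reproduce cohorts
  bit-for-bit.

## 5. Survival and group statistics

Kaplan–Meier curves come from lifelines; the median is computed directly
from the curve as the **smallest observed time with
$S(t) \le 0.5 + 10^{-12}$** (`math.inf` sentinel when the curve never
crosses 0.5), a convention that differs from lifelines'
`median_survival_time_` in some tie layouts. The log-rank test is a
hand-rolled Mantel–Haenszel accumulation (needed to expose O, E and V
and the O/E hazard ratio $\mathrm{HR} = (O_a/E_a)/(O_b/E_b)$ with CI
$\exp(\ln \mathrm{HR} \pm z \sqrt{1/E_a + 1/E_b})$), cross-checked
against lifelines in the tests. Event/censoring ties at the same time
follow the events-first convention. `group_compare` uses scipy Welch's t
and Mann–Whitney with `method="auto"`, which gives the exact null
distribution for small untied samples and the tie-corrected normal
approximation otherwise.

## 6. Dose–response fitting

4PL $v(d) = b + (t - b)/(1 + (d/\mathrm{IC}_{50})^h)$ fit by bounded
`scipy.optimize.least_squares` on residuals with IC50 parameterized as
$\log_{10}\mathrm{IC}_{50} \in [-3, 3]$, bottom/top in [0, 120], Hill in
[0.1, 10]. Multi-start over a Hill × log-IC50 grid (3 × 6 starts), best
residual sum wins; `fix_bottom`/`fix_top` pin the asymptotes for
constrained fits. The zero dose anchors the top asymptote but is excluded
from log-domain dose handling. Flat curves (mean viability drop across
dose tiers < 5 points) are flagged `no_inhibition` instead of returning
an arbitrary IC50; fits with bottom > top are reported unconverged.
Volumes: spheroid $V = \frac{4}{3}\pi r^3$; tumor
$v = \ell w^2 / 2$ by default, with an `"as-printed"` option for the
$(\ell / w^2)/2$ variant that appears in some reports.

## 7. Pipeline determinism

`run_pipeline` writes `summary.json` with sorted keys and rounded
floats; reruns of the same configuration are byte-identical. Every CSV
output carries a `# mycstratify v<version> config_hash=<sha256>` header;
the hash covers the configuration minus `out_dir`, because the hash
identifies the analysis, not its destination. Stage failures are
re-raised naming the failing stage.

## 8. Limitations

- The generator's shared effect size across the MYC-target block makes
  the learned up panel non-identifiable beyond block membership.
- The censoring scheme is informative by construction (see section 4);
  do not use censored synthetic cohorts to validate KM unbiasedness.
- Histology SDs and qPCR constants are plausible defaults, not published
  values.
- GSEA phenotype permutation requires at least 3 samples per group and
  its p-value granularity is limited by `n_perm`.
- The 4PL fit reports, but cannot rescue, IC50s far above the tested
  dose range when the asymptotes are left free; use the constrained fit
  for resistant lines.
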