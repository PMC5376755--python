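# mycstratify

Ratio-based MYC-activity stratification of pancreatic-cancer expression
profiles, with the downstream analyses that motivate the split: gene-set
enrichment, survival contrasts, and BET-inhibitor dose–response
pharmacology. A seeded synthetic-cohort generator reproduces the study
conditions end to end, so every statistical claim in the package can be
checked by parameter recovery.

## Scientific problem

Pancreatic ductal adenocarcinoma tumors vary widely in MYC pathway
activity, and MYC-high tumors behave differently in ways that matter
clinically: they proliferate faster, are less differentiated, carry worse
overall survival, and — crucially — are far more sensitive to BET
bromodomain inhibition (JQ1). A robust way to call a tumor MYC-high or
MYC-low from a small expression panel is therefore a candidate predictive
biomarker for BET-inhibitor therapy.

The classifier implemented here uses a 16-gene panel: 10 markers elevated
under high MYC activity (CDC20, KPNA2, PLK1, SRM, RFC4, MCM2, RUVBL2,
MAD2L1, CCT4, CAD) and 6 reciprocal markers elevated under low MYC
activity (VSIG2, BCL2L15, RAB25, TXNIP, CTSE, ERN2). Because it scores
each sample by *ratios* of up-markers to down-markers after a per-gene
normalization, the call is invariant to per-gene scale factors — the same
rule works across platforms (microarray, RNA-seq, qPCR) without
re-training.

## Core model

All classifier arithmetic is on the linear expression scale. For marker
gene $i$ and sample $\alpha$ in a cohort of $N$ samples:

1. **Mean-centered normalization.** Each marker row is rescaled to sum
   to 100 across the cohort:
   $\tilde u_{i\alpha} = 100\, u_{i\alpha} / \sum_{\beta} u_{i\beta}$.
   This removes per-gene scale (probe affinity, primer efficiency).
2. **Ratio matrix.** For each of the $10 \times 6 = 60$ (up, down) marker
   pairs: $r_{ij\alpha} = \tilde u_{i\alpha} / \tilde d_{j\alpha}$.
3. **Score and call.** The signature score is the median
   $\tilde m_\alpha$ of the 60 ratios. $\tilde m_\alpha > 1$ calls
   MYC-high; $\tilde m_\alpha < 1$ calls MYC-low; $\tilde m_\alpha = 1$
   is called MYC-low with a boundary flag.

Downstream, the package provides Kaplan–Meier curves and medians, a
Mantel–Haenszel log-rank test with an observed/expected hazard ratio,
weighted-KS gene-set enrichment with phenotype-permutation significance,
four-parameter-logistic (4PL) dose–response fitting
$v(d) = b + (t-b)/(1 + (d/\mathrm{IC}_{50})^h)$, ΔΔCt quantification for
qPCR input, and hierarchical-clustering stratification with
Welch-t/Benjamini–Hochberg marker ranking for learning a panel de novo.

## Worked example

Simulate a 55-patient cohort at the study defaults (17 MYC-high, 38
MYC-low) and score it with the default panel:

```python
from mycstratify.simulate import CohortConfig, generate_cohort
from mycstratify.signature import score_cohort

cfg = CohortConfig(n_background_genes=200, seed=1)
cohort = generate_cohort(cfg)
scores = score_cohort(cohort.expression)
print(scores.head(5))
print((scores["label"] == cohort.true_labels).mean())
```

```
              score     label  boundary_flag
sample_id
S001       0.457782   MYC-low          False
S002       5.678346  MYC-high          False
S003       0.564053   MYC-low          False
S004       5.418640  MYC-high          False
S005       0.394921   MYC-low          False
1.0
```

Survival contrast on a larger uncensored cohort (group medians 9.2 and
18.8 months by construction):

```python
from mycstratify.simulate import generate_survival
from mycstratify.outcomes import survival_summary

cfg = CohortConfig(n_patients=300, n_background_genes=50,
                   censor_rate=0.0, seed=1)
cohort = generate_cohort(cfg)
print(survival_summary(generate_survival(cohort.true_labels, cfg)))
```

```
{'median_a': 11.817, 'median_b': 17.698, 'chi2': 15.477,
 'pvalue': 8.4e-05, 'hazard_ratio': 1.609, 'hr_ci95': [1.224, 2.116],
 'n_a': 93, 'n_b': 207, 'events_a': 93, 'events_b': 207}
```

Refit the IC50 of a noiseless MYC-high chemogram:

```python
from mycstratify.simulate import generate_chemogram
from mycstratify.pharm import fit_dose_response_4pl

fit = fit_dose_response_4pl(
    generate_chemogram("MYC-high", CohortConfig(viab_noise_sd=0.0, seed=1)))
print(fit.ic50, fit.hill, fit.bottom, fit.top)
```

```
2.3 1.0 0.0 100.0
```

## Command line

The `mycstratify` console script wraps the same functionality:

```
mycstratify simulate --n 55 --frac-high 0.309 --seed 1 --out cohort/
mycstratify score --expr cohort/expression.tsv --scale linear --out scores.csv
mycstratify survival --meta cohort/metadata.csv
mycstratify run --config run.yaml        # full pipeline from a YAML config
```

`mycstratify run` executes simulate/load → stratify → rank → panel →
score → GSEA → survival → chemogram and writes a deterministic
`summary.json` (byte-identical across reruns of the same configuration);
every CSV output carries a header comment with the package version and a
configuration hash.

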