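"""Seeded synthetic cohort generator.

Emulates the statistical structure of a two-stratum pancreatic-cancer PDX
cohort: a MYC-target gene block elevated in the MYC-high stratum, six
reciprocal down-markers elevated in the MYC-low stratum, background genes with
no group effect, exponential survival with distinct group medians, 4PL
dose-response chemograms with distinct group IC50s, ordinal histology scores
and a qPCR Ct table for the 16-marker panel.

All randomness flows from ``CohortConfig.seed`` through per-generator
sub-streams, so identical configurations reproduce cohorts bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import DEFAULT_PANEL, DoseResponseSeries, ExpressionMatrix, MarkerPanel

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_survival",
    "generate_chemogram",
    "generate_histo_scores",
    "generate_qpcr",
    "standard_doses",
    "four_param_logistic",
]

HIGH, LOW = "MYC-high", "MYC-low"


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the published study conditions: 17/55 prevalence of the
    MYC-high stratum, overall-survival medians 9.2 / 18.8 months, JQ1 IC50
    means 2.3 / 39.22 uM, Ki67 means 2.88 / 2.06 (0-4 scale) and
    differentiation means 0.77 / 1.82 (0-2 scale).
    """

    n_patients: int = 55
    frac_high: float = 17 / 55
    n_background_genes: int = 1000
    n_myc_targets: int = 239            # includes the 10 up-markers
    panel_log2fc: float = 2.0           # up-markers in high; down-markers in low
    noise_sd: float = 0.5               # log2-scale Gaussian noise
    baseline_mean: float = 7.0          # per-gene baseline log2 level (RMA-like range)
    baseline_sd: float = 1.5
    surv_median_high: float = 9.2       # months
    surv_median_low: float = 18.8
    censor_rate: float = 0.25
    ic50_high: float = 2.3              # uM
    ic50_low: float = 39.22
    hill: float = 1.0
    viab_noise_sd: float = 5.0          # percentage points
    ki67_mean_high: float = 2.88
    ki67_mean_low: float = 2.06
    ki67_sd: float = 1.0
    diff_mean_high: float = 0.77
    diff_mean_low: float = 1.82
    diff_sd: float = 0.6
    qpcr_ct0: float = 35.0              # Ct of a transcript at unit linear expression
    qpcr_ref_ct: float = 12.0           # abundant 28S-like reference gene
    qpcr_noise_sd: float = 0.15         # cycles
    n_chemogram_lines_per_group: int = 4
    dose_max: float = 30.0              # uM
    dose_min_nonzero: float = 0.1
    n_doses: int = 10                   # 0 plus 9 log-spaced nonzero doses
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 <= self.frac_high <= 1.0:
            raise ValueError("frac_high must lie in [0, 1]")
        for name in ("n_background_genes", "n_myc_targets", "n_doses", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("surv_median_high", "surv_median_low", "ic50_high", "ic50_low",
                     "hill", "baseline_sd", "dose_max", "dose_min_nonzero"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("noise_sd", "viab_noise_sd", "ki67_sd", "diff_sd",
                     "qpcr_noise_sd", "censor_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.censor_rate > 1:
            raise ValueError("censor_rate must lie in [0, 1]")
        if self.n_myc_targets < len(DEFAULT_PANEL.up_genes):
            raise ValueError("n_myc_targets must cover the 10 up-markers")

    def spawn_rngs(self, names: tuple) -> dict:
        """Deterministic per-generator random streams derived from the seed."""
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(names))
        return {name: np.random.default_rng(child) for name, child in zip(names, children)}


@dataclass
class SyntheticCohort:
    """All synthetic study material for one simulated cohort."""

    expression: ExpressionMatrix                 # linear scale
    true_labels: pd.Series                       # sample_id -> MYC-high/MYC-low
    survival: pd.DataFrame                       # sample_id, time_months, event, group
    histo_scores: pd.DataFrame                   # sample_id, ki67, diff
    chemograms: list                             # DoseResponseSeries per cell line
    qpcr: pd.DataFrame                           # sample_id, gene, ct (long)
    panel: MarkerPanel = field(default_factory=lambda: DEFAULT_PANEL)
    myc_target_genes: tuple = ()
    config: CohortConfig | None = None

    @property
    def all_censored(self) -> bool:
        return bool((self.survival["event"] == 0).all())


def _assign_labels(config: CohortConfig, rng: np.random.Generator) -> pd.Series:
    """Exact-quota labels: round(frac_high * n) samples are MYC-high."""
    n = config.n_patients
    n_high = int(round(config.frac_high * n))
    if n_high in (0, n):
        warnings.warn(
            f"frac_high={config.frac_high} with n={n} yields a single-group cohort",
            UserWarning,
        )
    labels = np.array([HIGH] * n_high + [LOW] * (n - n_high))
    rng.shuffle(labels)
    ids = [f"S{i + 1:03d}" for i in range(n)]
    return pd.Series(labels, index=pd.Index(ids, name="sample_id"), name="group")


def _gene_roster(config: CohortConfig, panel: MarkerPanel):
    """Gene identifiers: up-markers + extra MYC targets + down-markers + background."""
    n_extra = config.n_myc_targets - panel.n_up
    extra_targets = tuple(f"MYCT{i + 1:04d}" for i in range(n_extra))
    myc_targets = panel.up_genes + extra_targets
    background = tuple(f"BG{i + 1:04d}" for i in range(config.n_background_genes))
    genes = myc_targets + panel.down_genes + background
    return genes, myc_targets


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort under the configured study conditions.

    Expression model per gene g, sample a (log2 scale)::

        x_ga = baseline_g + effect_g * 1{group condition} + N(0, noise_sd)

    where effect_g = ``panel_log2fc`` for MYC-target genes in MYC-high samples
    and for down-markers in MYC-low samples, and 0 for background genes.  The
    stored matrix is linear scale (2**x), strictly positive.
    """
    config.validate()
    panel = DEFAULT_PANEL
    rngs = config.spawn_rngs(("labels", "expression", "survival", "histo", "chemo", "qpcr"))

    labels = _assign_labels(config, rngs["labels"])
    genes, myc_targets = _gene_roster(config, panel)

    rng = rngs["expression"]
    n_genes, n = len(genes), config.n_patients
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
    high_mask = (labels.to_numpy() == HIGH).astype(float)

    effect = np.zeros((n_genes, n))
    target_rows = [i for i, g in enumerate(genes) if g in set(myc_targets)]
    down_rows = [i for i, g in enumerate(genes) if g in set(panel.down_genes)]
    effect[target_rows, :] = config.panel_log2fc * high_mask
    effect[down_rows, :] = config.panel_log2fc * (1.0 - high_mask)

    log2_expr = baseline[:, None] + effect + rng.normal(0.0, config.noise_sd, size=(n_genes, n))
    expr = ExpressionMatrix(
        pd.DataFrame(np.exp2(log2_expr), index=pd.Index(genes, name="gene"),
                     columns=labels.index),
        scale="linear",
    )

    survival = generate_survival(labels, config, rng=rngs["survival"])
    histo = generate_histo_scores(labels, config, rng=rngs["histo"])

    chemograms = []
    for grp, prefix in ((HIGH, "H"), (LOW, "L")):
        for k in range(config.n_chemogram_lines_per_group):
            chemograms.append(
                generate_chemogram(grp, config, cell_id=f"{prefix}{k + 1}",
                                   rng=rngs["chemo"])
            )

    qpcr = generate_qpcr(labels, config, expression=expr, rng=rngs["qpcr"])

    return SyntheticCohort(
        expression=expr, true_labels=labels, survival=survival, histo_scores=histo,
        chemograms=chemograms, qpcr=qpcr, panel=panel,
        myc_target_genes=myc_targets, config=config,
    )


def generate_survival(
    labels: pd.Series,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential survival times with group-specific medians, plus censoring.

    Event times are Exponential(rate = ln2 / median_group), so the true
    survival median equals the configured group median exactly.  A record is
    selected for censoring with probability ``censor_rate``; selected records
    are censored at a Uniform(0, min(T, 3*median)) time, guaranteeing
    event = 0 for every selected record.
    """
    if len(labels) == 0:
        raise ValueError("labels must be nonempty")
    if config.surv_median_high <= 0 or config.surv_median_low <= 0:
        raise ValueError("survival medians must be positive")
    if rng is None:
        rng = config.spawn_rngs(("labels", "expression", "survival"))["survival"]

    medians = np.where(labels.to_numpy() == HIGH,
                       config.surv_median_high, config.surv_median_low)
    rates = np.log(2.0) / medians
    event_times = rng.exponential(1.0 / rates)

    censored = rng.random(len(labels)) < config.censor_rate
    times = event_times.copy()
    cap = np.minimum(event_times, 3.0 * medians)
    times[censored] = rng.uniform(0.0, cap[censored])
    times = np.maximum(times, np.finfo(float).tiny)

    out = pd.DataFrame({
        "sample_id": labels.index,
        "time_months": times,
        "event": (~censored).astype(int),
        "group": labels.to_numpy(),
    })
    if censored.all():
        warnings.warn("all survival records are censored", UserWarning)
    return out


def standard_doses(config: CohortConfig | None = None) -> np.ndarray:
    """The 10-point dose ladder: 0 plus log-spaced nonzero doses up to dose_max."""
    cfg = config or CohortConfig()
    nonzero = np.geomspace(cfg.dose_min_nonzero, cfg.dose_max, cfg.n_doses - 1)
    return np.concatenate([[0.0], nonzero])


def four_param_logistic(dose, bottom: float, top: float, hill: float, ic50: float):
    """4PL viability curve; dose 0 maps to the top asymptote."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        frac = np.where(dose > 0, (dose / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + frac)


def generate_chemogram(
    label: str,
    config: CohortConfig,
    cell_id: str = "C1",
    rng: np.random.Generator | None = None,
) -> DoseResponseSeries:
    """Triplicate 4PL dose-response series for one cell line of a given stratum."""
    if label not in (HIGH, LOW):
        raise ValueError(f"label must be {HIGH!r} or {LOW!r}")
    config.validate()
    if rng is None:
        rng = config.spawn_rngs(("chemo",))["chemo"]

    ic50 = config.ic50_high if label == HIGH else config.ic50_low
    doses = standard_doses(config)
    rows = []
    for dose in doses:
        mean_v = four_param_logistic(dose, 0.0, 100.0, config.hill, ic50)
        for rep in range(1, config.n_replicates + 1):
            v = mean_v + rng.normal(0.0, config.viab_noise_sd) if config.viab_noise_sd > 0 else mean_v
            rows.append({"dose_uM": dose, "replicate": rep,
                         "viability_pct": max(float(v), 0.0)})
    return DoseResponseSeries(cell_id=cell_id, data=pd.DataFrame(rows), group=label)


def generate_histo_scores(
    labels: pd.Series,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Ordinal Ki67 (0-4) and differentiation (0-2) scores per sample."""
    if len(labels) == 0:
        raise ValueError("labels must be nonempty")
    if rng is None:
        rng = config.spawn_rngs(("histo",))["histo"]

    is_high = labels.to_numpy() == HIGH
    ki67_mean = np.where(is_high, config.ki67_mean_high, config.ki67_mean_low)
    diff_mean = np.where(is_high, config.diff_mean_high, config.diff_mean_low)
    ki67 = np.clip(np.rint(rng.normal(ki67_mean, config.ki67_sd)), 0, 4).astype(int)
    diff = np.clip(np.rint(rng.normal(diff_mean, config.diff_sd)), 0, 2).astype(int)
    return pd.DataFrame({"sample_id": labels.index, "ki67": ki67, "diff": diff,
                         "group": labels.to_numpy()})


def generate_qpcr(
    labels: pd.Series,
    config: CohortConfig,
    expression: ExpressionMatrix | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Ct table for the 16 panel markers plus the reference gene.

    Ct = ct0 - log2(linear expression) + N(0, qpcr_noise_sd); the reference
    gene has a constant mean Ct in every sample, so delta-delta-Ct quantities
    recapitulate the expression fold structure.
    """
    if len(labels) == 0:
        raise ValueError("labels must be nonempty")
    config.validate()
    if rng is None:
        rng = config.spawn_rngs(("qpcr",))["qpcr"]
    panel = DEFAULT_PANEL

    if expression is None:
        expression = generate_cohort(config).expression
    linear = expression.to_linear().values

    rows = []
    for sample in labels.index:
        for gene in panel.all_genes:
            ct = config.qpcr_ct0 - np.log2(linear.at[gene, sample])
            if config.qpcr_noise_sd > 0:
                ct += rng.normal(0.0, config.qpcr_noise_sd)
            rows.append({"sample_id": sample, "gene": gene, "ct": float(ct)})
        ref_ct = config.qpcr_ref_ct
        if config.qpcr_noise_sd > 0:
            ref_ct += rng.normal(0.0, config.qpcr_noise_sd)
        rows.append({"sample_id": sample, "gene": "RNA28S", "ct": float(ref_ct)})
    return pd.DataFrame(rows)


def config_to_dict(config: CohortConfig) -> dict:
    return asdict(config)
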