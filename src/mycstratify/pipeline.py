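"""End-to-end pipeline orchestrator.

One reproducible run ties together: simulate (or load) a cohort, discover
strata by clustering over the MYC-target panel, rank differential expression
and select the 16-marker panel, score the ratio signature, run permutation
GSEA, compute survival statistics by signature label, and fit chemograms.
Everything lands in a run directory with a machine-readable ``summary.json``;
two runs with the same configuration and seed produce byte-identical
summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import DEFAULT_PANEL
from .enrichment import GeneSetCollection, gsea_significance
from .io import header_comment, read_expression, read_gmt, read_panel, write_panel
from .outcomes import survival_summary
from .pharm import fit_dose_response_4pl, ic50_group_summary
from .signature import score_cohort
from .simulate import CohortConfig, SyntheticCohort, generate_cohort
from .stratify import count_increased, hclust_two_groups, select_marker_panel, ttest_rank

logger = logging.getLogger("mycstratify")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulate`` (a :class:`CohortConfig`) or
    ``expression_path`` must be provided.  In file mode the MYC-target gene
    list comes from the first set of ``targets_gmt``.
    """

    out_dir: str = "run"
    simulate: CohortConfig | None = None
    validation: CohortConfig | None = None     # optional second simulated cohort
    expression_path: str | None = None
    expression_scale: str = "linear"
    metadata_path: str | None = None
    chemogram_path: str | None = None
    targets_gmt: str | None = None
    gene_sets_gmt: str | None = None
    panel: str = "learned"                     # "learned" | "default" | path to JSON
    n_perm: int = 1000
    n_random_sets: int = 5                     # simulate-mode background gene sets
    random_set_size: int = 50
    seed: int | None = None

    def validate(self) -> None:
        if (self.simulate is None) == (self.expression_path is None):
            raise ValueError("provide exactly one of a simulate block or expression_path")
        if self.simulate is not None and self.seed is None:
            raise ValueError("seed is mandatory in simulate mode")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("simulate", "validation"):
            if raw.get(key) is not None:
                raw[key] = CohortConfig(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _config_hash(config: RunConfig) -> str:
    d = config.to_dict()
    d.pop("out_dir", None)  # the hash identifies the analysis, not its destination
    payload = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment(config_hash) + "\n")
        df.to_csv(fh, index=index)


def _simulate_gene_sets(cohort: SyntheticCohort, config: RunConfig) -> GeneSetCollection:
    """Planted MYC-target set plus seeded random background sets."""
    import numpy as np

    sets = {"MYC_TARGETS": list(cohort.myc_target_genes)}
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xBEEF]))
    background = [g for g in cohort.expression.genes if g.startswith("BG")]
    for k in range(config.n_random_sets):
        size = min(config.random_set_size, len(background))
        sets[f"RANDOM_{k + 1}"] = list(rng.choice(background, size=size, replace=False))
    return GeneSetCollection(sets=sets)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    config.validate()
    cfg_hash = _config_hash(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("mycstratify v%s config_hash=%s seed=%s", __version__, cfg_hash, config.seed)

    summary: dict = {"version": __version__, "config_hash": cfg_hash, "seed": config.seed}
    try:
        cohort = None
        if config.simulate is not None:
            stage = "simulate"
            sim_cfg = config.simulate
            sim_cfg.seed = int(config.seed)
            cohort = generate_cohort(sim_cfg)
            expr = cohort.expression
            myc_targets = list(cohort.myc_target_genes)
            metadata = cohort.survival.merge(cohort.histo_scores.drop(columns="group"),
                                             on="sample_id")
            _write_csv(expr.values, out / "expression.tsv", cfg_hash)
            _write_csv(metadata, out / "metadata.csv", cfg_hash, index=False)
            summary["n_patients"] = int(expr.n_samples)
            summary["n_true_high"] = int((cohort.true_labels == "MYC-high").sum())
        else:
            stage = "load"
            expr = read_expression(config.expression_path, scale=config.expression_scale)
            if config.targets_gmt is None:
                raise ValueError("file mode requires targets_gmt for stratification")
            targets = read_gmt(config.targets_gmt)
            myc_targets = targets.sets[next(iter(targets.sets))]
            metadata = (pd.read_csv(config.metadata_path, comment="#")
                        if config.metadata_path else None)
            summary["n_patients"] = int(expr.n_samples)

        stage = "stratify"
        labels = hclust_two_groups(expr, [g for g in myc_targets if g in set(expr.genes)])
        _write_csv(labels.rename("group").to_frame(), out / "labels.csv", cfg_hash)
        summary["n_cluster_high"] = int((labels == "MYC-high").sum())

        stage = "rank"
        ranked = ttest_rank(expr, labels)
        _write_csv(ranked, out / "ranked_genes.csv", cfg_hash)
        summary["n_targets_increased"] = count_increased(ranked, myc_targets)

        stage = "panel"
        if config.panel == "learned":
            panel = select_marker_panel(ranked, myc_targets)
        elif config.panel == "default":
            panel = DEFAULT_PANEL
        else:
            panel = read_panel(config.panel)
        write_panel(panel, out / "panel.json")
        summary["panel"] = {"up": list(panel.up_genes), "down": list(panel.down_genes)}

        stage = "score"
        scores = score_cohort(expr, panel, include_ratios=True)
        _write_csv(scores, out / "signature_scores.csv", cfg_hash)
        summary["n_signature_high"] = int((scores["label"] == "MYC-high").sum())
        if cohort is not None:
            agree = (scores["label"] == cohort.true_labels.loc[scores.index]).mean()
            summary["signature_agreement"] = round(float(agree), 6)

        stage = "gsea"
        if config.gene_sets_gmt is not None:
            collection = read_gmt(config.gene_sets_gmt)
        elif cohort is not None:
            collection = _simulate_gene_sets(cohort, config)
        else:
            collection = None
        if collection is not None and len(collection):
            report = gsea_significance(expr, labels, collection,
                                       n_perm=config.n_perm,
                                       seed=int(config.seed or 0))
            _write_csv(report, out / "enrichment.csv", cfg_hash)
            summary["enrichment"] = {
                name: {"nes": _round(row["nes"]), "fdr": _round(row["qvalue"])}
                for name, row in report.iterrows()
            }

        stage = "survival"
        if cohort is not None or metadata is not None:
            meta = metadata.merge(scores["label"].rename("signature_label"),
                                  left_on="sample_id", right_index=True)
            stats = survival_summary(meta, group_col="signature_label")
            with open(out / "survival.json", "w") as fh:
                json.dump(stats, fh, sort_keys=True, indent=2)
            summary["survival"] = {k: _round(v) for k, v in stats.items()
                                   if not isinstance(v, list)}
            summary["survival"]["hr_ci95"] = [_round(x) for x in stats["hr_ci95"]]

        stage = "chemogram"
        if cohort is not None:
            fits = {s.cell_id: fit_dose_response_4pl(s) for s in cohort.chemograms}
            line_groups = {s.cell_id: s.group for s in cohort.chemograms}
            fit_rows = pd.DataFrame([
                {"cell_id": cid, "group": line_groups[cid], "bottom": f.bottom,
                 "top": f.top, "hill": f.hill, "ic50": f.ic50, "rss": f.rss,
                 "converged": f.converged, "no_inhibition": f.no_inhibition}
                for cid, f in fits.items()
            ])
            _write_csv(fit_rows, out / "chemogram_fits.csv", cfg_hash, index=False)
            ic50s = ic50_group_summary(fits, line_groups)
            summary["ic50"] = {
                grp: {"mean": _round(row["mean"]), "sem": _round(row["sem"]),
                      "n": int(row["n"])}
                for grp, row in ic50s.iterrows()
            }
            if "welch_pvalue" in ic50s.attrs:
                summary["ic50"]["welch_pvalue"] = _round(ic50s.attrs["welch_pvalue"])

        stage = "validation"
        if config.validation is not None:
            val_cfg = config.validation
            if val_cfg.seed == 0:
                val_cfg.seed = int(config.seed) + 1
            val_cohort = generate_cohort(val_cfg)
            val_scores = score_cohort(val_cohort.expression, panel)
            _write_csv(val_scores, out / "validation_scores.csv", cfg_hash)
            val_agree = (val_scores["label"]
                         == val_cohort.true_labels.loc[val_scores.index]).mean()
            summary["validation"] = {
                "n_patients": int(val_cohort.expression.n_samples),
                "n_signature_high": int((val_scores["label"] == "MYC-high").sum()),
                "n_true_high": int((val_cohort.true_labels == "MYC-high").sum()),
                "agreement": round(float(val_agree), 6),
            }
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        logger.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=2)
        fh.write("\n")
    logger.info("run complete: %s", out)
    logger.removeHandler(handler)
    handler.close()
    return out


def _round(v, ndigits: int = 6):
    import math

    if v is None:
        return None
    try:
        f = float(v)
    except (TypeError, ValueError):
        return v
    if math.isnan(f):
        return None
    if math.isinf(f):
        return "inf"
    return round(f, ndigits)
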