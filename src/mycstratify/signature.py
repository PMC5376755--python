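"""Ratio-based MYC-activity signature classifier.

The classifier works on a small marker panel split into K up-markers (elevated
in MYC-high tumors) and L down-markers (elevated in MYC-low tumors).  For each
marker the raw linear expression is mean-center normalized across the cohort,

    u~_ia = u_ia * 100 / sum_a u_ia,

so every marker row sums to 100 over samples.  Each sample then gets the K*L
pairwise ratios r_ija = u~_ia / d~_ja between normalized up- and down-markers,
and the median of those ratios is the sample score: a median above 1 calls
MYC-high, below 1 MYC-low.  Because the normalization divides each marker by
its own cohort total, rescaling any single marker (platform calibration,
primer efficiency) cancels, which is what lets the same 16-gene panel serve
microarray and qPCR input.

The qPCR path converts Ct values to linear relative quantities by the
delta-delta-Ct rule (2**-ddCt against a reference gene and a calibrator
sample) and feeds them through the same formulas unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DEFAULT_PANEL, ExpressionMatrix, MarkerPanel, SignatureResult

__all__ = [
    "mean_center_normalize",
    "signature_ratios",
    "classify_signature",
    "score_cohort",
    "ddct_quantity",
    "expression_from_qpcr",
]

HIGH, LOW = "MYC-high", "MYC-low"


def mean_center_normalize(expr: ExpressionMatrix, markers) -> pd.DataFrame:
    """Normalize each marker row to percent-of-cohort-total.

    Input is converted to linear scale first (ratios of log2 values are not
    fold-change ratios).  Returns a marker x sample DataFrame whose rows each
    sum to 100.

    Raises
    ------
    KeyError
        If a marker is missing from the matrix.
    ValueError
        If any marker value is non-positive, or a marker's cohort total is 0.
    """
    markers = list(markers)
    linear = expr.to_linear().subset_genes(markers).values.astype(float)
    if linear.shape[1] < 1:
        raise ValueError("need at least one sample")
    bad = linear.index[(linear <= 0).any(axis=1)].tolist()
    if bad:
        raise ValueError(
            f"non-positive expression for markers {bad}; clean the input explicitly"
        )
    totals = linear.sum(axis=1)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero total expression for markers {zero}")
    return linear.mul(100.0 / totals, axis=0)


def signature_ratios(norm_up: pd.DataFrame, norm_down: pd.DataFrame, sample) -> np.ndarray:
    """All K*L normalized up/down ratios for one sample.

    Ratios are ordered up-marker-major: (up_1/down_1, up_1/down_2, ...).
    """
    if not norm_up.columns.equals(norm_down.columns):
        raise ValueError("up and down matrices must cover the same samples")
    if sample not in norm_up.columns:
        raise KeyError(f"unknown sample {sample!r}")
    u = norm_up[sample].to_numpy(dtype=float)
    d = norm_down[sample].to_numpy(dtype=float)
    if (d == 0).any():
        dead = norm_down.index[d == 0].tolist()
        raise ValueError(f"down-marker dropout (normalized value 0): {dead}")
    return (u[:, None] / d[None, :]).ravel()


def classify_signature(ratios, sample_id: str = "") -> SignatureResult:
    """Median-threshold call from a sample's ratio set.

    The score is the median of the ratios (mean of the two central order
    statistics for an even count).  Score > 1 calls MYC-high; score < 1 calls
    MYC-low; a score of exactly 1 is called MYC-low with ``boundary_flag``
    set, since both classes are defined by strict inequality.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("ratio list is empty")
    if not np.isfinite(ratios).all() or (ratios <= 0).any():
        raise ValueError("ratios must be finite and positive")
    score = float(np.median(ratios))
    if score > 1.0:
        label, boundary = HIGH, False
    else:
        label, boundary = LOW, score == 1.0
    return SignatureResult(sample_id=sample_id, ratios=ratios, score=score,
                           label=label, boundary_flag=boundary)


def score_cohort(
    expr: ExpressionMatrix,
    panel: MarkerPanel = DEFAULT_PANEL,
    include_ratios: bool = False,
) -> pd.DataFrame:
    """Score every sample in a cohort.

    Returns a DataFrame indexed by sample with columns ``score``, ``label``
    and ``boundary_flag``; with ``include_ratios=True`` a wide column per
    ratio (``r_<up>_<down>``) is appended.

    Note the cohort dependence: normalization divides by per-marker cohort
    totals, so a sample's score depends on which other samples are scored
    with it.
    """
    norm_up = mean_center_normalize(expr, panel.up_genes)
    norm_down = mean_center_normalize(expr, panel.down_genes)
    rows = []
    ratio_rows = []
    for sample in expr.samples:
        r = signature_ratios(norm_up, norm_down, sample)
        res = classify_signature(r, sample_id=str(sample))
        rows.append({"sample_id": sample, "score": res.score,
                     "label": res.label, "boundary_flag": res.boundary_flag})
        if include_ratios:
            ratio_rows.append(r)
    out = pd.DataFrame(rows).set_index("sample_id")
    if include_ratios:
        names = [f"r_{u}_{d}" for u in panel.up_genes for d in panel.down_genes]
        out = pd.concat(
            [out, pd.DataFrame(ratio_rows, index=out.index, columns=names)], axis=1
        )
    return out


def ddct_quantity(ct_target: float, ct_ref: float,
                  ct_target_cal: float, ct_ref_cal: float) -> float:
    """Relative quantity by the delta-delta-Ct rule.

    RQ = 2**-[(ct_target - ct_ref) - (ct_target_cal - ct_ref_cal)], the fold
    change of the target in the sample relative to a calibrator sample, both
    normalized to a reference gene.
    """
    cts = (ct_target, ct_ref, ct_target_cal, ct_ref_cal)
    if not all(np.isfinite(c) for c in cts):
        raise ValueError("all Ct values must be finite")
    ddct = (ct_target - ct_ref) - (ct_target_cal - ct_ref_cal)
    return float(2.0 ** (-ddct))


def expression_from_qpcr(
    ct_table: pd.DataFrame,
    reference_gene: str = "RNA28S",
    calibrator: str | None = None,
) -> ExpressionMatrix:
    """Convert a long Ct table to a linear relative-quantity matrix.

    ``ct_table`` has columns sample_id, gene, ct.  Each marker in each sample
    becomes 2**-ddCt against ``reference_gene`` and a calibrator sample (the
    first sample by default).  The calibrator choice only rescales genes by
    per-gene constants, which the signature normalization cancels.
    """
    required = {"sample_id", "gene", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    wide = ct_table.pivot_table(index="gene", columns="sample_id", values="ct",
                                aggfunc="mean")
    if reference_gene not in wide.index:
        raise KeyError(f"reference gene {reference_gene!r} not in Ct table")
    ref = wide.loc[reference_gene]
    targets = wide.drop(index=reference_gene)
    if calibrator is None:
        calibrator = targets.columns[0]
    if calibrator not in targets.columns:
        raise KeyError(f"calibrator sample {calibrator!r} not in Ct table")

    dct = targets.sub(ref, axis=1)                 # per-sample delta-Ct
    ddct = dct.sub(dct[calibrator], axis=0)        # against the calibrator
    rq = 2.0 ** (-ddct)
    return ExpressionMatrix(rq, scale="linear")
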