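"""Core data containers shared across the analysis pipeline.

The central object is :class:`ExpressionMatrix`, a genes x samples table with an
explicit scale tag.  Microarray pipelines (RMA) emit log2-scale values while the
qPCR relative-quantity path is inherently linear; every downstream formula in
the signature classifier is defined on the linear scale, so the tag is mandatory
and conversion happens exactly once, on demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MarkerPanel",
    "DEFAULT_PANEL",
    "SignatureResult",
    "DoseResponseSeries",
]

_VALID_SCALES = ("log2", "linear")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a declared scale.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with sample identifiers as
        columns.  Identifiers must be unique on both axes.
    scale
        ``"log2"`` for RMA-like values, ``"linear"`` for natural-scale
        intensities or qPCR relative quantities.
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in _VALID_SCALES:
            raise ValueError(f"scale must be one of {_VALID_SCALES}, got {self.scale!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        dup_genes = self.values.index[self.values.index.duplicated()].unique().tolist()
        if dup_genes:
            raise ValueError(f"duplicate gene identifiers: {dup_genes}")
        dup_samples = self.values.columns[self.values.columns.duplicated()].unique().tolist()
        if dup_samples:
            raise ValueError(f"duplicate sample identifiers: {dup_samples}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_linear(self) -> "ExpressionMatrix":
        """Return a linear-scale view; log2 input is exponentiated exactly once."""
        if self.scale == "linear":
            return self
        return ExpressionMatrix(np.exp2(self.values), scale="linear")

    def to_log2(self) -> "ExpressionMatrix":
        if self.scale == "log2":
            return self
        if (self.values <= 0).any().any():
            raise ValueError("cannot log2-transform a matrix with non-positive entries")
        return ExpressionMatrix(np.log2(self.values), scale="log2")

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes missing from the expression matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)], scale=self.scale)


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered up-marker / down-marker gene lists for the ratio signature.

    The default 16-gene panel (10 transcripts elevated in MYC-high tumors,
    6 elevated in MYC-low) yields 60 pairwise ratios per sample.
    """

    up_genes: tuple = ()
    down_genes: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "up_genes", tuple(self.up_genes))
        object.__setattr__(self, "down_genes", tuple(self.down_genes))
        if len(self.up_genes) < 1 or len(self.down_genes) < 1:
            raise ValueError("panel needs at least one up-marker and one down-marker")
        if len(set(self.up_genes)) != len(self.up_genes):
            raise ValueError("duplicate up-marker identifiers")
        if len(set(self.down_genes)) != len(self.down_genes):
            raise ValueError("duplicate down-marker identifiers")
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValueError(f"genes present in both marker lists: {sorted(overlap)}")

    @property
    def n_up(self) -> int:
        return len(self.up_genes)

    @property
    def n_down(self) -> int:
        return len(self.down_genes)

    @property
    def n_ratios(self) -> int:
        return self.n_up * self.n_down

    @property
    def all_genes(self) -> tuple:
        return self.up_genes + self.down_genes

    def swapped(self) -> "MarkerPanel":
        """Panel with up/down roles exchanged (maps the score m to 1/m)."""
        return MarkerPanel(up_genes=self.down_genes, down_genes=self.up_genes)


#: The published 16-marker MYC-activity panel: 10 MYC-target transcripts
#: elevated in MYC-high tumors and 6 transcripts elevated in MYC-low tumors.
DEFAULT_PANEL = MarkerPanel(
    up_genes=(
        "CDC20", "KPNA2", "PLK1", "SRM", "RFC4",
        "MCM2", "RUVBL2", "MAD2L1", "CCT4", "CAD",
    ),
    down_genes=("VSIG2", "BCL2L15", "RAB25", "TXNIP", "CTSE", "ERN2"),
)


@dataclass
class SignatureResult:
    """Per-sample classifier output: ratio set, median score and call."""

    sample_id: str
    ratios: np.ndarray
    score: float
    label: str  # "MYC-high" | "MYC-low"
    boundary_flag: bool = False


@dataclass
class DoseResponseSeries:
    """One cell line's chemogram: replicate viabilities over a dose ladder."""

    cell_id: str
    data: pd.DataFrame = field(default_factory=pd.DataFrame)
    # long format: columns dose_uM, replicate, viability_pct
    group: str | None = None

    def __post_init__(self) -> None:
        required = {"dose_uM", "replicate", "viability_pct"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"chemogram table needs columns {sorted(required)}")
        if (self.data["dose_uM"] < 0).any():
            raise ValueError("doses must be nonnegative")
        if not np.isfinite(self.data["viability_pct"]).all():
            raise ValueError("viability values must be finite")

    @property
    def doses(self) -> np.ndarray:
        return np.unique(self.data["dose_uM"].to_numpy())


def is_undefined_median(value: float) -> bool:
    """True for the sentinel used when a KM curve never crosses S = 0.5."""
    return value is None or math.isinf(value) or (isinstance(value, float) and math.isnan(value))
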