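"""Readers and writers for the pipeline's text formats.

Expression matrices come in as TSV/CSV (genes as rows, header = sample IDs) or
GCT v1.2; gene-set collections as GMT; sample metadata, chemograms and qPCR Ct
tables as CSV.  Every file the pipeline writes starts with a comment line
declaring the tool version and the run's configuration hash, so outputs are
traceable to the exact run that produced them.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd

from . import __version__
from .containers import ExpressionMatrix, MarkerPanel
from .enrichment import GeneSetCollection

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_panel",
    "write_panel",
    "header_comment",
]


def header_comment(config_hash: str = "unhashed") -> str:
    return f"# mycstratify v{__version__} config_hash={config_hash}"


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "txt"):
        return "tsv"
    if suffix in ("csv", "gct"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass fmt explicitly")


def read_expression(path, fmt: str | None = None, scale: str = "linear") -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV, CSV or GCT v1.2.

    ``scale`` declares whether the stored values are log2 or linear; the tag
    travels with the matrix and governs the single exponentiation applied
    before ratio-based scoring.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "gct":
        df = _read_gct(path)
    else:
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    non_numeric = df.columns[df.dtypes == object].tolist()
    if non_numeric:
        raise ValueError(f"non-numeric expression columns: {non_numeric}")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate gene identifiers: {dup}")
    return ExpressionMatrix(df, scale=scale)


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2", "1.2"):
            raise ValueError(f"unsupported GCT version line: {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ValueError("malformed GCT dimensions line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t")
    if body.shape[0] != n_rows or body.shape[1] - 2 != n_cols:
        raise ValueError(
            f"GCT declares {n_rows} x {n_cols} but body is "
            f"{body.shape[0]} x {body.shape[1] - 2}"
        )
    body = body.set_index(body.columns[0]).drop(columns=[body.columns[1]])
    body.index.name = "gene"
    return body


def write_expression(expr: ExpressionMatrix, path, fmt: str | None = None,
                     config_hash: str = "unhashed") -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
            out = expr.values.copy()
            out.insert(0, "Description", "na")
            out.index.name = "Name"
            out.to_csv(fh, sep="\t")
        return
    sep = "\t" if fmt == "tsv" else ","
    with open(path, "w") as fh:
        fh.write(header_comment(config_hash) + "\n")
        expr.values.to_csv(fh, sep=sep)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT gene-set file: name <tab> description <tab> members...

    Duplicate members within a set are dropped with a warning; duplicate set
    names and short lines are errors.
    """
    path = Path(path)
    sets, descriptions = {}, {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        warnings.warn(f"{path.name}: empty gene-set file", UserWarning)
        return GeneSetCollection()
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path.name}:{lineno}: expected >= 3 tab-separated fields")
        name, desc, members = fields[0], fields[1], [f for f in fields[2:] if f]
        if name in sets:
            raise ValueError(f"{path.name}:{lineno}: duplicate set name {name!r}")
        unique = list(dict.fromkeys(members))
        if len(unique) < len(members):
            warnings.warn(f"{path.name}:{lineno}: duplicate members in {name!r} deduplicated",
                          UserWarning)
        sets[name] = unique
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_panel(path) -> MarkerPanel:
    """Marker panel from JSON ({"up_genes": [...], "down_genes": [...]})."""
    with open(path) as fh:
        obj = json.load(fh)
    return MarkerPanel(up_genes=tuple(obj["up_genes"]), down_genes=tuple(obj["down_genes"]))


def write_panel(panel: MarkerPanel, path) -> None:
    with open(path, "w") as fh:
        json.dump({"up_genes": list(panel.up_genes),
                   "down_genes": list(panel.down_genes)}, fh, indent=2)
        fh.write("\n")
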