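"""Readers and writers for expression matrices, trait tables and gene sets.

TSV is the canonical interchange format; ``.csv`` files are detected by
extension.  Expression files carry feature identifiers in the first
column and sample identifiers in the header row (a transpose flag
handles samples-in-rows files).  Gene sets are read from GMT files
(``name<TAB>description<TAB>gene1<TAB>gene2...``) or from two-column
(gene, set) tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleNetworkError,
    TraitTable,
)

logger = logging.getLogger("samplenet")

__all__ = [
    "read_expression",
    "write_expression",
    "read_traits",
    "read_gene_sets",
    "RunConfig",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path,
    orientation: str = "genes_in_rows",
    missing_token: str = "NA",
) -> ExpressionMatrix:
    """Read a delimited expression matrix with identifiers."""
    path = Path(path)
    if not path.exists():
        raise SampleNetworkError(f"no such file: {path}")
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise SampleNetworkError(f"unknown orientation: {orientation}")
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    ids = header[1:]
    if len(ids) != len(set(ids)):
        raise SampleNetworkError("duplicate identifier")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=[missing_token])
    except pd.errors.ParserError as exc:
        raise SampleNetworkError("malformed table") from exc
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise SampleNetworkError("duplicate identifier")
    non_numeric = df.apply(pd.to_numeric, errors="coerce")
    if (non_numeric.isna() & df.notna()).any().any():
        raise SampleNetworkError("non-numeric cell in expression matrix")
    if orientation == "samples_in_rows":
        non_numeric = non_numeric.T
    return ExpressionMatrix(non_numeric)


def write_expression(expr: ExpressionMatrix, path) -> None:
    path = Path(path)
    expr.data.to_csv(path, sep=_sep_for(path), index_label="feature")


def read_traits(path) -> TraitTable:
    """Read a per-sample covariate table (first column: sample ids)."""
    path = Path(path)
    if not path.exists():
        raise SampleNetworkError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return TraitTable(df)


def read_gene_sets(path) -> GeneSetCollection:
    """Read gene sets from a GMT file or a two-column (gene, set) table.

    A line whose extension is ``.gmt`` is parsed as
    ``name<TAB>description<TAB>gene...``; anything else is read as a
    delimited two-column table.  Duplicate genes within a set are
    removed (counted in ``n_duplicates_removed``); empty set lines are
    skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise SampleNetworkError(f"no such file: {path}")
    sets: dict[str, list[str]] = {}
    n_dups = 0
    if path.suffix.lower() == ".gmt":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            name, genes = fields[0], [g for g in fields[2:] if g]
            if not genes:
                warnings.warn(f"empty gene set line skipped: {name}", stacklevel=2)
                continue
            deduped = list(dict.fromkeys(genes))
            n_dups += len(genes) - len(deduped)
            sets[name] = deduped
    else:
        df = pd.read_csv(path, sep=_sep_for(path))
        if df.shape[1] < 2:
            raise SampleNetworkError("two-column (gene, set) table required")
        gene_col, set_col = df.columns[:2]
        for name, block in df.groupby(set_col, sort=False):
            genes = [str(g) for g in block[gene_col]]
            deduped = list(dict.fromkeys(genes))
            n_dups += len(genes) - len(deduped)
            sets[str(name)] = deduped
    if not sets:
        raise SampleNetworkError("no gene sets read")
    return GeneSetCollection(sets=sets, n_duplicates_removed=n_dups)


@dataclasses.dataclass
class RunConfig:
    """Serializable record of one command-line run, for reproducibility."""

    command: str
    expr_path: str | None = None
    traits_path: str | None = None
    sets_path: str | None = None
    corr_method: str = "pearson"
    beta: float = 2.0
    kind: str = "signed_cor"
    zk_threshold: float = -2.0
    max_rounds: int = 10
    group_by: str | None = None
    mode: str = "separate"
    seed: int = 0
    out_dir: str = "."

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "run_config.json").write_text(
            json.dumps(dataclasses.asdict(self), indent=2) + "\n"
        )
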