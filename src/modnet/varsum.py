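"""Variant-classification count summaries.

Candidate modifier genes are profiled against population and clinical
variant archives (gnomAD annotation classes; ClinVar clinical
significance classes).  This module ingests the per-gene count tables
and reproduces the summary arithmetic: column totals, percentages, and
per-column leading genes.

Two conventions matter and are enforced here:

* a ``-`` cell means the gene is absent from the source (e.g. a gene
  with no ClinVar germline submissions) and is *excluded* from totals
  and denominators — missing is not zero;
* percentages are truncated (toward zero) at one decimal place, the
  convention consistent with the published figures.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

GNOMAD_COLUMNS = ("all", "missense", "synonymous")
CLINVAR_COLUMNS = ("all", "b_lb", "p_lp", "ci", "vus")


class CountParseError(ValueError):
    """A count cell is negative, fractional, or otherwise not a count."""


def read_counts(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a variant-class count TSV into a typed table.

    First column: gene symbol; remaining columns: integer counts, with
    ``-`` denoting a missing cell (gene absent from the source, stored
    as NA).  ``schema`` is ``"gnomad"`` or ``"clinvar"`` and sets the
    minimum expected columns.
    """
    required = {"gnomad": GNOMAD_COLUMNS, "clinvar": CLINVAR_COLUMNS}.get(schema)
    if required is None:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    gene_col = df.columns[0]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CountParseError(f"{path}: schema {schema!r} missing columns {missing}")
    out = pd.DataFrame(index=pd.Index(df[gene_col].str.upper(), name="gene"))
    for col in df.columns[1:]:
        cells = []
        for raw in df[col]:
            raw = str(raw).strip()
            if raw in ("-", "", "nan"):
                cells.append(pd.NA)
                continue
            try:
                val = int(raw)
            except ValueError as exc:
                raise CountParseError(
                    f"{path}: column {col!r}: {raw!r} is not an integer count"
                ) from exc
            if val < 0:
                raise CountParseError(f"{path}: column {col!r}: negative count {val}")
            cells.append(val)
        out[col] = pd.array(cells, dtype="Int64")
    return out


def total(table: pd.DataFrame, column: str) -> int:
    """Sum of a count column over the genes present in the source."""
    if column not in table.columns:
        raise KeyError(f"unknown column {column!r}")
    return int(table[column].dropna().sum())


def fraction(
    table: pd.DataFrame,
    numerator_column: str,
    gene: str = "ALL",
    denominator_column: str = "all",
) -> float:
    """Percentage ``100 * num / den`` truncated to one decimal place.

    With ``gene="ALL"`` both terms are column totals over present
    cells; otherwise the two cells of the named gene are used.
    Truncation is toward zero via integer arithmetic, so the result
    never exceeds the untruncated value.
    """
    for col in (numerator_column, denominator_column):
        if col not in table.columns:
            raise KeyError(f"unknown column {col!r}")
    if gene == "ALL":
        num = total(table, numerator_column)
        den = total(table, denominator_column)
    else:
        gene = gene.upper()
        if gene not in table.index:
            raise KeyError(f"unknown gene {gene!r}")
        num_cell = table.at[gene, numerator_column]
        den_cell = table.at[gene, denominator_column]
        if pd.isna(num_cell) or pd.isna(den_cell):
            raise ValueError(f"gene {gene!r} has missing cells for this fraction")
        num, den = int(num_cell), int(den_cell)
    if den == 0:
        raise ZeroDivisionError("denominator count is zero")
    return (1000 * num // den) / 10.0


def argmax_gene(table: pd.DataFrame, column: str) -> str:
    """Gene with the maximal count in a column (ties: smallest symbol)."""
    if column not in table.columns:
        raise KeyError(f"unknown column {column!r}")
    col = table[column].dropna()
    if col.empty:
        raise ValueError(f"column {column!r} has no present cells")
    top = int(col.max())
    winners = sorted(col.index[col == top])
    if len(winners) > 1:
        warnings.warn(
            f"argmax tie in column {column!r}: {winners}; returning {winners[0]}",
            stacklevel=2,
        )
    return winners[0]


def write_counts(table: pd.DataFrame, path: str | Path) -> None:
    """Write a count table back to TSV, restoring ``-`` for missing."""
    out = table.astype(object).where(table.notna(), "-")
    out.to_csv(path, sep="\t")
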