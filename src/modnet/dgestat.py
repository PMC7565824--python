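"""Differential-expression stage.

The pipeline needs, per gene, a log2 fold change and an FDR-adjusted
p-value for a two-group contrast (e.g. disease-gene knockdown vs
control).  The statistic here is the Welch two-sample t test on
log2-scale expression with Benjamini-Hochberg adjustment — a defined,
calibrated stand-in for off-the-shelf moderated-t/NB pipelines, which
this package deliberately does not clone.  Precomputed DGE tables from
any external tool can be imported instead via :func:`load_dge_table`.

A DGETable is a DataFrame indexed by gene with columns ``logFC`` (log2
units, case minus control), ``p``, ``q`` (BH-adjusted) and
``significant`` (q < alpha).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class DGEIntegrityError(ValueError):
    """An imported DGE table violates its numeric contract."""


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values; ``q < alpha`` reproduces step-up."""
    _, q, _, _ = multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")
    return q


def dge_contrast(
    expr: pd.DataFrame,
    groups: pd.Series | Mapping[str, str],
    case: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential expression on a log2 expression matrix.

    ``expr`` is genes x samples; ``groups`` maps each sample column to
    one of exactly two labels.  ``case`` names the label whose mean is
    the minuend of logFC (default: the lexicographically larger label,
    so ``control`` vs anything else does the expected thing).  p-values
    come from Welch's t (Welch-Satterthwaite df, two-sided); q from BH
    over all tested genes.  Genes with zero variance in both groups are
    flagged with p = 1 and a warning.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    groups = groups.reindex(expr.columns)
    if groups.isna().any():
        raise ValueError("groups must label every sample column")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    if case is None:
        case = levels[1]
    if case not in levels:
        raise ValueError(f"case label {case!r} not among {levels}")
    control = levels[0] if case == levels[1] else levels[1]
    case_cols = groups.index[groups == case]
    ctrl_cols = groups.index[groups == control]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need at least 2 samples per group")

    x = expr[case_cols].to_numpy(float)
    y = expr[ctrl_cols].to_numpy(float)
    logfc = x.mean(axis=1) - y.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
    flat = (x.var(axis=1, ddof=1) == 0) & (y.var(axis=1, ddof=1) == 0)
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} gene(s) constant within both groups; p set to 1",
            stacklevel=2,
        )
    p = np.where(np.isnan(p) | flat, 1.0, p)
    q = bh_adjust(p)
    return pd.DataFrame(
        {"logFC": logfc, "p": p, "q": q, "significant": q < alpha},
        index=expr.index.rename("gene"),
    )


def load_dge_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Import a precomputed DGE table (TSV).

    ``schema`` maps the canonical names ``gene``, ``logFC``, ``p``,
    ``q`` to the file's column names; by default those names are used
    directly.  A missing q column is recomputed from p by BH.  Range
    checks enforce p, q in (0, 1] and q >= p; violations raise
    :class:`DGEIntegrityError` — a table with q < p cannot have been
    BH-adjusted over the rows shown.
    """
    colmap = {"gene": "gene", "logFC": "logFC", "p": "p", "q": "q"}
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "logFC") if colmap[c] not in df.columns]
    if missing:
        raise DGEIntegrityError(f"{path}: missing required column(s) {missing}")
    has_p = colmap["p"] in df.columns
    has_q = colmap["q"] in df.columns
    if not (has_p or has_q):
        raise DGEIntegrityError(f"{path}: need a p or q column")
    out = pd.DataFrame(index=pd.Index(df[colmap["gene"]].str.upper(), name="gene"))
    out["logFC"] = df[colmap["logFC"]].to_numpy(float)
    if has_p:
        p = df[colmap["p"]].to_numpy(float)
        if ((p <= 0) | (p > 1)).any():
            raise DGEIntegrityError(f"{path}: p-values must lie in (0, 1]")
        out["p"] = p
    if has_q:
        q = df[colmap["q"]].to_numpy(float)
        if ((q <= 0) | (q > 1)).any():
            raise DGEIntegrityError(f"{path}: q-values must lie in (0, 1]")
        out["q"] = q
    else:
        out["q"] = bh_adjust(out["p"].to_numpy())
    if not has_p:
        out["p"] = out["q"]  # conservative: treat q as an upper bound on p
    if (out["q"] < out["p"] - 1e-12).any():
        raise DGEIntegrityError(f"{path}: q < p — not a valid BH adjustment")
    out["significant"] = out["q"] < alpha
    return out


def write_dge_table(dge: pd.DataFrame, path: str | Path) -> None:
    dge.to_csv(path, sep="\t")
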