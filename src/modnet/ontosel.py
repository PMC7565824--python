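"""Ontology-driven gene-set selection.

Candidate modifier genes for a monogenic disease are seeded from two
annotation namespaces: Gene Ontology biological processes (the *forward*
genetics direction, gene function toward phenotype) and Human Phenotype
Ontology terms (the *reverse* direction, phenotype toward genes).  This
module parses the two standard association formats (GAF 2.x and the HPO
``genes_to_phenotype`` table), derives gene sets from curated term-ID
lists, and compares the resulting sets Venn-style.

Gene identity is the plain upper-cased HGNC-style symbol; no alias
resolution is attempted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)


class Namespace(Enum):
    """Annotation namespace an :class:`AnnotationSet` was drawn from."""

    GO_BP = "GO_BP"
    HPO = "HPO"


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of upper-cased gene symbols."""

    genes: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes

    def __or__(self, other: "GeneSet") -> "GeneSet":
        return GeneSet(self.genes | other.genes, f"{self.label}|{other.label}")

    def __and__(self, other: "GeneSet") -> "GeneSet":
        return GeneSet(self.genes & other.genes, f"{self.label}&{other.label}")


@dataclass
class AnnotationSet:
    """Mapping term-ID -> gene set for one annotation namespace.

    Invariants: term IDs are unique (dict keys), gene symbols are
    non-empty upper-case strings, and no term maps to the empty set.
    """

    namespace: Namespace
    terms: dict[str, frozenset[str]] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        self.terms = {
            t: frozenset(g.upper() for g in gs) for t, gs in self.terms.items() if gs
        }

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self.terms.values():
            out |= gs
        return frozenset(out)

    def n_associations(self) -> int:
        return sum(len(gs) for gs in self.terms.values())


class AnnotationParseError(ValueError):
    """A malformed row or missing column in an annotation file."""


def read_gaf(path: str | Path) -> AnnotationSet:
    """Read a GO annotation file (GAF 2.x tab layout).

    Column 2 (1-based index 3) carries the gene symbol, column 5 the GO
    term ID and column 4 the qualifier.  Rows whose qualifier contains
    ``NOT`` are negative annotations and are dropped; comment lines
    starting with ``!`` are ignored.  Duplicate gene-term pairs collapse
    to one association.
    """
    path = Path(path)
    terms: dict[str, set[str]] = {}
    with path.open(newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 15:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: GAF row has {len(cols)} columns, "
                    "expected at least 15"
                )
            symbol, qualifier, term_id = cols[2], cols[3], cols[4]
            if "NOT" in qualifier.split("|"):
                continue
            if not symbol:
                continue
            terms.setdefault(term_id, set()).add(symbol.upper())
    if not terms:
        warnings.warn(f"{path}: no usable GO associations found", stacklevel=2)
    return AnnotationSet(
        namespace=Namespace.GO_BP,
        terms={t: frozenset(gs) for t, gs in terms.items()},
        source=str(path),
    )


def read_hpo_assoc(
    path: str | Path,
    gene_column: str = "gene_symbol",
    term_column: str = "hpo_id",
) -> AnnotationSet:
    """Read an HPO ``genes_to_phenotype``-dialect TSV.

    The header row is detected by the presence of the required column
    names (a leading ``#`` is tolerated).  Rows for the same term are
    merged into one gene set.  Windows line endings are accepted.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh if ln.strip()]
    if not lines:
        raise AnnotationParseError(f"{path}: empty file")
    header = lines[0].lstrip("#").split("\t")
    try:
        gi = header.index(gene_column)
        ti = header.index(term_column)
    except ValueError as exc:
        raise AnnotationParseError(
            f"{path}: required columns {gene_column!r}/{term_column!r} "
            f"not found in header {header!r}"
        ) from exc
    terms: dict[str, set[str]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        cols = line.split("\t")
        if len(cols) <= max(gi, ti):
            raise AnnotationParseError(f"{path}: line {lineno}: too few columns")
        symbol, term_id = cols[gi].strip(), cols[ti].strip()
        if symbol and term_id:
            terms.setdefault(term_id, set()).add(symbol.upper())
    return AnnotationSet(
        namespace=Namespace.HPO,
        terms={t: frozenset(gs) for t, gs in terms.items()},
        source=str(path),
    )


def genes_for_terms(
    ann: AnnotationSet, term_ids: Iterable[str], label: str = ""
) -> GeneSet:
    """Union of the gene sets of the selected terms.

    Unknown term IDs are reported with a warning; if *all* requested
    IDs are unknown the selection is empty by error, not silently.
    """
    term_ids = list(term_ids)
    if not term_ids:
        raise ValueError("term_ids must be nonempty")
    unknown = [t for t in term_ids if t not in ann.terms]
    if len(unknown) == len(term_ids):
        raise KeyError(f"none of the requested term IDs are known: {unknown}")
    if unknown:
        warnings.warn(f"unknown term IDs skipped: {unknown}", stacklevel=2)
    genes: set[str] = set()
    for t in term_ids:
        genes |= ann.terms.get(t, frozenset())
    return GeneSet(frozenset(genes), label or f"{ann.namespace.value} selection")


def venn_counts(a: GeneSet, b: GeneSet) -> tuple[int, int, int]:
    """Two-set Venn partition sizes ``(only_a, only_b, both)``."""
    both = len(a.genes & b.genes)
    return len(a.genes) - both, len(b.genes) - both, both


def write_gmt(sets: Mapping[str, GeneSet] | Iterable[GeneSet], path: str | Path) -> None:
    """Write gene sets in GMT format (name, description, genes per line)."""
    if isinstance(sets, Mapping):
        items = [(name, gs) for name, gs in sets.items()]
    else:
        items = [(gs.label or f"set{i}", gs) for i, gs in enumerate(sets)]
    with Path(path).open("w") as fh:
        for name, gs in items:
            fh.write("\t".join([name, gs.label or name, *sorted(gs.genes)]) + "\n")


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read a GMT file into labelled gene sets."""
    out: dict[str, GeneSet] = {}
    with Path(path).open(newline="") as fh:
        for line in fh:
            cols = line.rstrip("\r\n").split("\t")
            if len(cols) < 3:
                continue
            out[cols[0]] = GeneSet(frozenset(cols[2:]), label=cols[1])
    return out
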