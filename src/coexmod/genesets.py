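"""GMT gene-set I/O and GO-term eligibility filtering.

Gene sets are read and written in the MSigDB GMT dialect: one set per line,
``name<TAB>description<TAB>gene1<TAB>gene2...``.  Identifiers are matched
case-sensitively by exact string; symbol translation is out of scope.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from .data import ExpressionMatrix


class GmtParseError(ValueError):
    """Raised for malformed GMT lines; carries the 1-based line number."""


@dataclasses.dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def gene_set(self) -> set[str]:
        return set(self.genes)


@dataclasses.dataclass
class GeneSetCollection:
    """Ordered list of uniquely named gene sets with a category tag."""

    sets: list[GeneSet]
    category: str = "go_bp"  # go_bp | evidence | regulator

    def __post_init__(self):
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene-set names in collection")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def get(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


def read_gmt(path, category: str = "go_bp") -> GeneSetCollection:
    """Parse a GMT file.  Duplicate genes within a line are deduplicated
    (first occurrence wins); empty lines are skipped; a line with fewer than
    three fields raises :class:`GmtParseError` naming the line number."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets.append(GeneSet(name, description, tuple(genes)))
    return GeneSetCollection(sets, category=category)


def write_gmt(collection: GeneSetCollection, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def filter_by_size(
    collection: GeneSetCollection,
    expr_genes,
    min_size: int = 50,
    max_size: int = 500,
) -> GeneSetCollection:
    """Keep sets with ``min_size <= |set ∩ expr_genes| <= max_size`` (inclusive
    bounds); returned sets carry the intersected ("measured") membership, in
    the original gene order."""
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    expr_genes = set(expr_genes)
    kept = []
    for s in collection:
        measured = tuple(g for g in s.genes if g in expr_genes)
        if min_size <= len(measured) <= max_size:
            kept.append(GeneSet(s.name, s.description, measured))
    return GeneSetCollection(kept, category=collection.category)


def term_expression(matrix: ExpressionMatrix, gene_set: GeneSet) -> ExpressionMatrix:
    """Row-subset of ``matrix`` restricted to the set's measured genes (kept in
    the matrix's gene order), original sample order.  Requires >=2 measured
    genes."""
    members = gene_set.gene_set()
    genes = [g for g in matrix.gene_ids if g in members]
    if len(genes) < 2:
        raise ValueError(
            f"gene set {gene_set.name!r} overlaps the matrix in "
            f"{len(genes)} genes (<2)"
        )
    return matrix.subset_genes(genes)
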