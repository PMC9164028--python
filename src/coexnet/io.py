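"""On-disk formats and in-memory domain types.

All pipeline artifacts are plain tab-delimited UTF-8 text:

* expression matrix — header row of sample IDs, first column gene IDs,
  non-negative finite values, no missing entries;
* network edge list — headerless rows ``gene_a  gene_b  correlation
  [pvalue [fdr]]``, one unordered pair per row;
* annotation — two columns ``gene_id  term_id``, repeated pairs allowed;
* gene list — one ID per line, ``#`` comments ignored.

Readers validate strictly and fail loudly (missing values are rejected:
correlations on incomplete pairs would silently change the sample count).
Writers emit Unix line endings and 6 significant digits, so
write-read-write is byte stable after the first read canonicalizes edge
order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import LoadError, CoexnetError

logger = logging.getLogger("coexnet")

__all__ = [
    "ExpressionMatrix",
    "CoexpressionNetwork",
    "AnnotationMap",
    "ModulePartition",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_network",
    "write_network",
    "read_annotation",
    "write_annotation",
    "read_gene_list",
]


def _fmt(x: float) -> str:
    """Format a number with 6 significant digits, integers without exponent."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return format(x, ".6g")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """A genes x samples table of non-negative expression values.

    Units are whatever the upstream quantification produced (counts, TPM,
    normalized values) — the toolkit treats them as unitless.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique, non-empty identifier sequences.
    values
        Array of shape ``(len(gene_ids), len(sample_ids))``; finite, >= 0.
    """

    __slots__ = ("gene_ids", "sample_ids", "values", "_gene_index")

    def __init__(self, gene_ids, sample_ids, values):
        self.gene_ids = list(gene_ids)
        self.sample_ids = list(sample_ids)
        self.values = np.asarray(values, dtype=float)
        self._validate()
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    def _validate(self):
        if not self.gene_ids:
            raise CoexnetError("expression matrix has no genes")
        if not self.sample_ids:
            raise CoexnetError("expression matrix has no samples")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise CoexnetError(f"duplicate gene IDs: {dup[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CoexnetError("duplicate sample IDs")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise CoexnetError(
                f"value shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise CoexnetError("expression values must be finite (no NaN/inf)")
        if np.any(self.values < 0):
            raise CoexnetError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self._gene_index[gene]]

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same genes/samples, new values."""
        return ExpressionMatrix(self.gene_ids, self.sample_ids, values)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = [self._gene_index[g] for g in genes]
        return ExpressionMatrix(list(genes), self.sample_ids, self.values[idx])

    def __eq__(self, other):
        return (
            isinstance(other, ExpressionMatrix)
            and self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self):
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Lexicographically ordered unordered pair; self-pairs are an error."""
    if a == b:
        raise CoexnetError(f"self-edge on gene {a!r}")
    return (a, b) if a < b else (b, a)


class CoexpressionNetwork:
    """Undirected weighted gene graph stored as a canonical edge dict.

    Each unordered pair is stored once under lexicographic order
    ``gene_a < gene_b``; the weight is the correlation (in [-1, 1]);
    p-value and FDR are optional (``None`` when absent). Nodes are exactly
    the genes incident to at least one edge.
    """

    __slots__ = ("_edges", "_adj")

    def __init__(self, edges=None):
        # (a, b) -> (weight, pvalue, fdr)
        self._edges: dict[tuple[str, str], tuple[float, float | None, float | None]] = {}
        self._adj: dict[str, set[str]] = {}
        if edges is not None:
            for e in edges:
                self.add_edge(*e)

    def add_edge(self, a, b, weight, pvalue=None, fdr=None):
        key = canonical_pair(a, b)
        weight = float(weight)
        if not math.isfinite(weight) or not (-1.0 <= weight <= 1.0):
            raise CoexnetError(f"edge weight {weight} for {key} outside [-1, 1]")
        if key in self._edges:
            if self._edges[key] != (weight, pvalue, fdr):
                raise CoexnetError(
                    f"duplicate edge {key} with conflicting values "
                    f"{self._edges[key]} vs {(weight, pvalue, fdr)}"
                )
            return  # idempotent duplicate
        self._edges[key] = (weight, pvalue, fdr)
        self._adj.setdefault(key[0], set()).add(key[1])
        self._adj.setdefault(key[1], set()).add(key[0])

    # -- queries ------------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def has_edge(self, a, b) -> bool:
        try:
            return canonical_pair(a, b) in self._edges
        except CoexnetError:
            return False

    def weight(self, a, b) -> float:
        return self._edges[canonical_pair(a, b)][0]

    def neighbors(self, gene: str) -> set[str]:
        return self._adj.get(gene, set())

    def degree(self, gene: str) -> int:
        return len(self._adj.get(gene, ()))

    def edges(self):
        """Iterate ``(gene_a, gene_b, weight, pvalue, fdr)`` in canonical order."""
        for (a, b) in sorted(self._edges):
            w, p, f = self._edges[(a, b)]
            yield a, b, w, p, f

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self._edges)

    def __eq__(self, other):
        return isinstance(other, CoexpressionNetwork) and self._edges == other._edges

    def __repr__(self):
        return f"CoexpressionNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


class AnnotationMap:
    """Bidirectional gene <-> functional-term index.

    Term IDs are opaque strings (GO/KEGG-style labels); no ontology
    structure is assumed. The two indices are exact inverses and empty
    term sets are never stored.
    """

    __slots__ = ("gene_to_terms", "term_to_genes")

    def __init__(self, pairs=None):
        self.gene_to_terms: dict[str, set[str]] = {}
        self.term_to_genes: dict[str, set[str]] = {}
        if pairs is not None:
            for g, t in pairs:
                self.add(g, t)

    def add(self, gene: str, term: str):
        self.gene_to_terms.setdefault(gene, set()).add(term)
        self.term_to_genes.setdefault(term, set()).add(gene)

    @property
    def genes(self) -> set[str]:
        return set(self.gene_to_terms)

    @property
    def terms(self) -> set[str]:
        return set(self.term_to_genes)

    def terms_of(self, gene: str) -> set[str]:
        return self.gene_to_terms.get(gene, set())

    def genes_of(self, term: str) -> set[str]:
        return self.term_to_genes.get(term, set())

    def without_gene(self, gene: str) -> "AnnotationMap":
        """Copy with one gene's annotations hidden (for leave-one-out)."""
        out = AnnotationMap()
        for g, terms in self.gene_to_terms.items():
            if g == gene:
                continue
            for t in terms:
                out.add(g, t)
        return out

    def __len__(self):
        return len(self.gene_to_terms)

    def __eq__(self, other):
        return (
            isinstance(other, AnnotationMap)
            and self.gene_to_terms == other.gene_to_terms
        )


@dataclass
class ModulePartition:
    """Disjoint gene modules plus the unassigned remainder.

    ``modules`` are pairwise-disjoint gene sets; together with
    ``unassigned`` they cover exactly the network's nodes.
    """

    modules: list[frozenset]
    unassigned: set = field(default_factory=set)

    def module_of(self, gene: str):
        """Index of the module containing *gene*, or None if unassigned."""
        for i, m in enumerate(self.modules):
            if gene in m:
                return i
        return None

    @property
    def assigned(self) -> set:
        out = set()
        for m in self.modules:
            out |= m
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_lines(path):
    with open(path, encoding="utf-8", newline="") as fh:
        for raw in fh:
            yield raw.rstrip("\r\n")


def read_expression_matrix(path) -> ExpressionMatrix:
    """Load an expression TSV.

    The header's first token is arbitrary; the remaining tokens are sample
    IDs. Every data row must carry the gene ID plus one numeric value per
    sample. Duplicate genes, ragged rows, negative or non-numeric cells
    are load errors that name the offending line.
    """
    lines = _read_lines(path)
    try:
        header = next(lines)
    except StopIteration:
        raise LoadError(f"{path}: empty file") from None
    sample_ids = header.split("\t")[1:]
    if not sample_ids:
        raise LoadError(f"{path}: header has no sample columns")
    gene_ids: list[str] = []
    seen: set[str] = set()
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines, start=2):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 1 + len(sample_ids):
            raise LoadError(
                f"{path}:{lineno}: expected {1 + len(sample_ids)} fields, "
                f"got {len(fields)}"
            )
        gene = fields[0]
        if gene in seen:
            raise LoadError(f"{path}:{lineno}: duplicate gene ID {gene!r}")
        seen.add(gene)
        row = []
        for col, tok in enumerate(fields[1:], start=1):
            try:
                v = float(tok)
            except ValueError:
                raise LoadError(
                    f"{path}:{lineno}: non-numeric value {tok!r} in column "
                    f"{col} (sample {sample_ids[col - 1]!r})"
                ) from None
            if not math.isfinite(v):
                raise LoadError(
                    f"{path}:{lineno}: non-finite value in column {col}"
                )
            if v < 0:
                raise LoadError(
                    f"{path}:{lineno}: negative value {v} in column {col}"
                )
            row.append(v)
        gene_ids.append(gene)
        rows.append(row)
    if not gene_ids:
        raise LoadError(f"{path}: no data rows")
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float))


def write_expression_matrix(m: ExpressionMatrix, path):
    """Write an expression TSV (6 significant digits)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\t" + "\t".join(m.sample_ids) + "\n")
        for g, row in zip(m.gene_ids, m.values):
            fh.write(g + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_network(path) -> CoexpressionNetwork:
    """Load a headerless edge-list TSV.

    Columns: ``gene_a  gene_b  correlation [pvalue [fdr]]``; empty strings
    mark absent statistics. Pairs are canonicalized on read; a repeated
    pair is accepted only with identical values.
    """
    net = CoexpressionNetwork()
    for lineno, line in enumerate(_read_lines(path), start=1):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 3 or len(fields) > 5:
            raise LoadError(f"{path}:{lineno}: expected 3-5 fields, got {len(fields)}")
        a, b = fields[0], fields[1]
        try:
            w = float(fields[2])
            p = float(fields[3]) if len(fields) > 3 and fields[3] != "" else None
            f = float(fields[4]) if len(fields) > 4 and fields[4] != "" else None
        except ValueError:
            raise LoadError(f"{path}:{lineno}: non-numeric edge statistic") from None
        try:
            net.add_edge(a, b, w, p, f)
        except CoexnetError as exc:
            raise LoadError(f"{path}:{lineno}: {exc}") from None
    return net


def write_network(net: CoexpressionNetwork, path):
    """Write a 5-column edge list; absent statistics become empty strings."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b, w, p, f in net.edges():
            fh.write(
                "\t".join(
                    [
                        a,
                        b,
                        _fmt(w),
                        _fmt(p) if p is not None else "",
                        _fmt(f) if f is not None else "",
                    ]
                )
                + "\n"
            )


def read_annotation(path) -> AnnotationMap:
    """Load a two-column ``gene  term`` TSV; repeated pairs are deduplicated."""
    ann = AnnotationMap()
    for lineno, line in enumerate(_read_lines(path), start=1):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise LoadError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        ann.add(fields[0], fields[1])
    return ann


def write_annotation(ann: AnnotationMap, path):
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in sorted(ann.gene_to_terms):
            for t in sorted(ann.gene_to_terms[g]):
                fh.write(f"{g}\t{t}\n")


def read_gene_list(path) -> list[str]:
    """Load a one-ID-per-line list; ``#`` comments ignored, duplicates dropped.

    An empty result is an error: callers (e.g. housekeeping normalization)
    require at least one gene.
    """
    out: list[str] = []
    seen: set[str] = set()
    for line in _read_lines(path):
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        if token in seen:
            logger.warning("duplicate gene %r in list %s dropped", token, path)
            continue
        seen.add(token)
        out.append(token)
    if not out:
        raise LoadError(f"{path}: gene list is empty")
    return out
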