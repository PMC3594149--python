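"""Gene→GO annotations, gene lists, propagation, and the reference genome.

Genes and proteins are treated as one identifier space throughout; counts
are cardinalities of *distinct* gene sets, never annotation-line counts,
so multiple evidence lines for the same (gene, term) pair never double
count. Annotation propagation applies the true-path rule: a gene
annotated to a term is implicitly annotated to every ancestor of that
term along the traversal relations.

The reference genome size N can be supplied by the user or estimated from
a gene-ID table: gene identifiers are grouped by name class (Primary,
Synonym, ordered-locus, ORF) and the class with the most distinct ids is
taken as the genome gene count — for Streptococcus pneumoniae this picks
the ordered-locus class.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .errors import ConfigError, DataError
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

NAME_CLASSES = ("Primary", "Synonym", "ordered-locus", "ORF")

#: Tie-break priority for the genome-size class arg-max (highest first).
CLASS_PRIORITY = ("ordered-locus", "Primary", "ORF", "Synonym")


@dataclass
class AnnotationSet:
    """Direct and propagated gene↔GO indexes.

    ``direct`` maps gene_id → set of GO ids from the annotation file;
    ``propagated`` maps term_id → set of gene_ids after ancestor closure
    (empty until :func:`propagate` is called). ``skip_report`` counts
    dropped annotation lines by reason.
    """

    direct: dict[str, set[str]] = field(default_factory=dict)
    propagated: dict[str, set[str]] = field(default_factory=dict)
    skip_report: Counter = field(default_factory=Counter)

    @property
    def n_pairs(self) -> int:
        return sum(len(v) for v in self.direct.values())

    def genes(self) -> set[str]:
        return set(self.direct)


@dataclass
class Sample:
    """A named gene list; ``size`` is the number of distinct genes."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        dups = 0
        for g in self.genes:
            if g in seen:
                dups += 1
            else:
                seen[g] = None
        if dups:
            logger.warning("sample %s: collapsed %d duplicate gene id(s)", self.name, dups)
        self.genes = tuple(seen)

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def gene_set(self) -> set[str]:
        return set(self.genes)


@dataclass
class ReferenceGenome:
    """Genome-wide GO index: per-term gene counts K_i and genome size N."""

    per_go_counts: dict[str, int]
    genome_size: int
    size_source: str  # "estimated" or "user_supplied"
    name_class_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [t for t, k in self.per_go_counts.items() if k > self.genome_size]
        if bad:
            raise DataError(
                f"genome size {self.genome_size} smaller than K for {bad[0]}"
            )


# -- readers ------------------------------------------------------------


def load_gene_list(path: str | Path, name: str | None = None) -> Sample:
    """Read a plain-text gene list (one id per line, '#' comments)."""
    path = Path(path)
    genes = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    if not genes:
        raise DataError(f"gene list {path} is empty")
    return Sample(name=name or path.stem, genes=tuple(genes))


def load_annotations(
    path: str | Path, format: str, graph: OntologyGraph
) -> AnnotationSet:
    """Load gene→GO annotations from GAF 2.x or two-column TSV.

    Annotations to unknown or obsolete terms are dropped and counted in
    the skip report; GAF lines carrying a NOT qualifier are excluded.
    An empty file is an error, not an empty annotation set.
    """
    path = Path(path)
    if format not in {"gaf", "tsv"}:
        raise ConfigError(f"unknown annotation format {format!r}")
    ann = AnnotationSet()
    obsolete = set(graph.skipped)

    def add(gene: str, go_id: str) -> None:
        if go_id in obsolete:
            ann.skip_report["obsolete_term"] += 1
            return
        if go_id not in graph.terms:
            ann.skip_report["unknown_term"] += 1
            return
        ann.direct.setdefault(gene, set()).add(go_id)

    n_lines = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if format == "gaf":
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise DataError(f"{path}:{lineno}: GAF line has {len(cols)} columns")
            n_lines += 1
            qualifier = cols[3]
            if "NOT" in qualifier.split("|"):
                ann.skip_report["not_qualifier"] += 1
                continue
            gene = cols[1] or cols[0]
            add(gene, cols[4])
        else:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            cols = stripped.split("\t")
            if len(cols) < 2:
                raise DataError(f"{path}:{lineno}: expected gene_id<TAB>go_id")
            n_lines += 1
            add(cols[0], cols[1])
    if n_lines == 0:
        raise DataError(f"annotation file {path} contains no annotation lines")
    if ann.skip_report:
        logger.warning("annotation skip report for %s: %s", path, dict(ann.skip_report))
    return ann


# -- propagation --------------------------------------------------------


def propagate(ann: AnnotationSet, graph: OntologyGraph) -> AnnotationSet:
    """Apply the true-path rule: each term collects the genes of all its
    descendants (union of direct annotation sets, distinct-gene semantics).

    Returns a new :class:`AnnotationSet` sharing the direct map, with the
    ``propagated`` index filled for every term of the graph.
    """
    if not ann.direct:
        logger.warning("propagating an empty annotation set")
    direct_by_term: dict[str, set[str]] = {t: set() for t in graph.terms}
    for gene, gos in ann.direct.items():
        for go in gos:
            direct_by_term[go].add(gene)

    tg = graph.traversal_graph()  # edges child -> parent
    propagated: dict[str, set[str]] = {}
    # children precede parents in a topological order of the child->parent DAG
    for term in nx.topological_sort(tg):
        acc = set(direct_by_term[term])
        for child, _parent in tg.in_edges(term):
            acc |= propagated[child]
        propagated[term] = acc
    return AnnotationSet(
        direct=ann.direct, propagated=propagated, skip_report=ann.skip_report
    )


# -- reference genome ----------------------------------------------------


def load_gene_id_table(path: str | Path) -> list[tuple[str, str]]:
    """Read a TSV of (gene_id, name_class) rows."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        cols = stripped.split("\t")
        if len(cols) < 2:
            raise DataError(f"{path}:{lineno}: expected gene_id<TAB>name_class")
        rows.append((cols[0], cols[1]))
    return rows


def estimate_genome_size(
    gene_id_table: Sequence[tuple[str, str]]
) -> tuple[str, int]:
    """Estimate genome gene count from a gene-ID table.

    Distinct gene ids are counted per name class and the class with the
    highest count wins; its count is the genome size N. Ties are broken
    by the fixed priority ordered-locus > Primary > ORF > Synonym.
    """
    if not gene_id_table:
        raise DataError("gene-ID table is empty")
    per_class: dict[str, set[str]] = {c: set() for c in NAME_CLASSES}
    for gene_id, name_class in gene_id_table:
        if name_class not in per_class:
            raise DataError(f"unknown gene name class {name_class!r}")
        per_class[name_class].add(gene_id)
    counts = {c: len(s) for c, s in per_class.items()}
    best = max(counts.values())
    winners = [c for c in counts if counts[c] == best]
    if len(winners) > 1:
        logger.warning("genome-size class tie between %s; using priority", winners)
    winner = min(winners, key=CLASS_PRIORITY.index)
    return winner, best


def build_reference(
    ann: AnnotationSet,
    graph: OntologyGraph,
    genome_size: int | None = None,
    gene_id_table: Sequence[tuple[str, str]] | None = None,
) -> ReferenceGenome:
    """Build the genome-wide GO index from propagated annotations.

    ``genome_size`` takes precedence when given; otherwise it is estimated
    from ``gene_id_table``. If the resulting N is smaller than the number
    of annotated genes it is raised to that count with a warning.
    """
    if not ann.propagated:
        ann = propagate(ann, graph)
    name_class_counts: dict[str, int] = {}
    if genome_size is not None:
        n, source = int(genome_size), "user_supplied"
    elif gene_id_table is not None:
        per_class: dict[str, set[str]] = {c: set() for c in NAME_CLASSES}
        for gid, cls in gene_id_table:
            if cls not in per_class:
                raise DataError(f"unknown gene name class {cls!r}")
            per_class[cls].add(gid)
        name_class_counts = {c: len(s) for c, s in per_class.items()}
        _, n = estimate_genome_size(gene_id_table)
        source = "estimated"
    else:
        raise ConfigError("either genome_size or gene_id_table must be supplied")

    n_annotated = len(ann.genes())
    if n < n_annotated:
        logger.warning(
            "genome size %d below annotated gene count %d; corrected", n, n_annotated
        )
        n = n_annotated
    per_go = {t: len(genes) for t, genes in ann.propagated.items()}
    return ReferenceGenome(
        per_go_counts=per_go,
        genome_size=n,
        size_source=source,
        name_class_counts=name_class_counts,
    )
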