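"""Per-scope GO distributions and the tabular gene-selection report.

A *navigation scope* picks the slice of the GO graph being looked at:
all terms at one level, the leaves (most specific terms), or the direct
children of one term. A sample's distribution at a scope counts, for
each term, the distinct sample genes in the term's propagated gene set.

The selection table lines up one GO term per row across an ordered list
of samples and reports the *rate of change* — the last sample's
(optionally normalized) count divided by the first sample's — together
with the common genes (intersection of the term's gene hits across all
samples) and the union genes. Terms with a strong rate of change are
candidates for further investigation; common genes are the genes driving
a shared process across all samples.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .annotation import AnnotationSet, Sample, propagate
from .errors import ConfigError, DataError, StatsError
from .ontology import OntologyGraph
from .stats import NormalizationPlan, normalization_coefficients

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Scope:
    """A navigation scope: one level, the leaves, or children of a term."""

    kind: str  # "level" | "leaves" | "children"
    namespace: str
    level: int | None = None
    term: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"level", "leaves", "children"}:
            raise ConfigError(f"unknown scope kind {self.kind!r}")
        if self.kind == "level" and (self.level is None or self.level < 0):
            raise ConfigError("level scope requires a non-negative level")
        if self.kind == "children" and not self.term:
            raise ConfigError("children scope requires a term id")

    def terms(self, graph: OntologyGraph) -> set[str]:
        if self.kind == "level":
            if self.level > graph.max_level(self.namespace):
                logger.warning(
                    "level %d beyond graph depth %d; empty scope",
                    self.level,
                    graph.max_level(self.namespace),
                )
                return set()
            return graph.nodes_at_level(self.namespace, self.level)
        if self.kind == "leaves":
            return graph.leaves(self.namespace)
        return graph.children_at(self.term)

    def __str__(self) -> str:
        if self.kind == "level":
            return f"{self.namespace}:level={self.level}"
        if self.kind == "leaves":
            return f"{self.namespace}:leaves"
        return f"{self.namespace}:children-of:{self.term}"


@dataclass(frozen=True)
class GODistribution:
    """GO term → gene count for one sample at one navigation scope."""

    scope: Scope
    counts: dict[str, float]
    units: str  # "raw" | "normalized" | "percent"
    sample_name: str
    n_annotated: int = 0  # distinct annotated sample genes in the namespace


@dataclass(frozen=True)
class SelectionRow:
    term_id: str
    term_name: str
    per_sample_counts: tuple[float, ...]
    rate_of_change: float | None
    common_genes: frozenset[str]
    union_genes: frozenset[str]

    @property
    def abs_log_rate(self) -> float | None:
        """|log rate|; infinite for a vanished term, None when undefined."""
        if self.rate_of_change is None:
            return None
        if self.rate_of_change == 0:
            return math.inf
        return abs(math.log(self.rate_of_change))


def distribution(
    sample: Sample,
    ann: AnnotationSet,
    graph: OntologyGraph,
    scope: Scope,
) -> GODistribution:
    """Raw per-GO gene counts of a sample at a navigation scope.

    counts[t] = |propagated gene set of t ∩ sample genes| for every term
    t in the scope.
    """
    if not ann.propagated:
        ann = propagate(ann, graph)
    genes = sample.gene_set
    counts = {
        t: float(len(ann.propagated[t] & genes)) for t in sorted(scope.terms(graph))
    }
    root = graph.root(scope.namespace)
    n_annotated = len(ann.propagated[root] & genes)
    return GODistribution(
        scope=scope,
        counts=counts,
        units="raw",
        sample_name=sample.name,
        n_annotated=n_annotated,
    )


def _row_sort_key(row: SelectionRow) -> tuple:
    alr = row.abs_log_rate
    # defined rates first, by |log rate| descending; ties and undefined by id
    return (alr is None, -(alr or 0.0), row.term_id)


def selection_table(
    samples: Sequence[Sample],
    ann: AnnotationSet,
    graph: OntologyGraph,
    scope: Scope,
    normalize: bool = False,
) -> list[SelectionRow]:
    """The tabular gene-selection report: one row per GO term in the scope
    with any nonzero count across the samples.

    Per-sample counts follow the given sample order (multiplied by the
    size-normalization coefficients when ``normalize`` is set). The rate
    of change is last / first; it is undefined (None) when the first
    sample's count is zero. Rows are ordered by |log rate| descending,
    ties by term id.
    """
    if len(samples) < 2:
        raise ConfigError("selection table needs at least 2 samples")
    if not ann.propagated:
        ann = propagate(ann, graph)
    if normalize:
        plan = normalization_coefficients(samples)
        coeffs = [plan.coefficients[s.name] for s in samples]
    else:
        coeffs = [1.0] * len(samples)

    rows = []
    for t in sorted(scope.terms(graph)):
        hit_sets = [ann.propagated[t] & s.gene_set for s in samples]
        raw = [len(h) for h in hit_sets]
        if not any(raw):
            continue
        counts = tuple(c * r for c, r in zip(coeffs, raw))
        rate = counts[-1] / counts[0] if counts[0] > 0 else None
        common = frozenset.intersection(*map(frozenset, hit_sets))
        union = frozenset.union(*map(frozenset, hit_sets))
        rows.append(
            SelectionRow(
                term_id=t,
                term_name=graph.terms[t].name,
                per_sample_counts=counts,
                rate_of_change=rate,
                common_genes=common,
                union_genes=union,
            )
        )
    rows.sort(key=_row_sort_key)
    return rows


def select_terms(
    table: Sequence[SelectionRow],
    min_fold: float,
    keep_novel: bool = False,
) -> list[SelectionRow]:
    """Keep rows whose rate of change is at least ``min_fold`` in either
    direction (≥ min_fold or ≤ 1/min_fold, boundaries inclusive).

    Rows with an undefined rate (term absent from the first sample) are
    kept only when ``keep_novel`` requests these newly appearing terms.
    """
    if min_fold <= 1:
        raise ConfigError(f"min_fold must be > 1, got {min_fold}")
    kept = []
    for row in table:
        r = row.rate_of_change
        if r is None:
            if keep_novel:
                kept.append(row)
        elif r >= min_fold or r <= 1.0 / min_fold:
            kept.append(row)
    return kept


# -- serialization -------------------------------------------------------


def table_to_tsv(
    table: Sequence[SelectionRow],
    sample_names: Sequence[str],
    metadata: Mapping[str, str] | None = None,
) -> str:
    """Selection table as TSV with a '#'-prefixed metadata header."""
    lines = [f"# {k}={v}" for k, v in (metadata or {}).items()]
    cols = (
        ["go_id", "go_name"]
        + [f"count_{n}" for n in sample_names]
        + ["rate_of_change", "common_genes", "union_genes"]
    )
    lines.append("\t".join(cols))
    for row in table:
        rate = "NA" if row.rate_of_change is None else f"{row.rate_of_change:.6g}"
        lines.append(
            "\t".join(
                [row.term_id, row.term_name]
                + [f"{c:.6g}" for c in row.per_sample_counts]
                + [rate, ",".join(sorted(row.common_genes)), ",".join(sorted(row.union_genes))]
            )
        )
    return "\n".join(lines) + "\n"


def table_to_json(
    table: Sequence[SelectionRow],
    sample_names: Sequence[str],
    metadata: Mapping[str, str] | None = None,
) -> str:
    payload = {
        "metadata": dict(metadata or {}),
        "samples": list(sample_names),
        "rows": [
            {
                "go_id": r.term_id,
                "go_name": r.term_name,
                "counts": list(r.per_sample_counts),
                "rate_of_change": r.rate_of_change,
                "common_genes": sorted(r.common_genes),
                "union_genes": sorted(r.union_genes),
            }
            for r in table
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
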