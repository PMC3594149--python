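"""Seeded toy fixtures: ontologies, annotations, genome tables, gene lists.

Every generator draws from its own explicitly seeded pseudo-random
stream (no global random state), so identical seeds yield byte-identical
OBO/GAF/gene-list files. The toy graphs are grown level by level — each
new term attaches to 1–2 existing parents — which guarantees a rooted
DAG by construction. Gene lists emulate per-niche lists of up- or
down-regulated genes: samples are drawn without replacement from the
annotated gene pool, and an optional *effect* map of term → enrichment
multiplier oversamples the genes under chosen terms in every sample
after the first, planting a known ground-truth direction for the
rate-of-change report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation import AnnotationSet, Sample, propagate
from .errors import ConfigError
from .ontology import GOTerm, OntologyGraph

_NS_ASPECT = {
    "molecular_function": "F",
    "biological_process": "P",
    "cellular_component": "C",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one toy dataset."""

    seed: int = 0
    n_terms: int = 50
    max_fanout: int = 4
    n_genes: int = 200
    annotations_per_gene: tuple[int, int] = (1, 4)
    namespace: str = "molecular_function"
    sample_sizes: tuple[int, ...] = (100, 50)
    effect: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_terms < 2:
            raise ConfigError("need at least 2 terms (root plus one child)")
        if self.n_genes < 1 or any(s < 1 for s in self.sample_sizes):
            raise ConfigError("all sizes must be >= 1")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _term_id(i: int) -> str:
    return f"GO:{i + 1:07d}"


def make_ontology(spec: FixtureSpec, path: str | Path | None = None) -> OntologyGraph:
    """Grow a random rooted GO DAG and optionally write it as OBO.

    Term 0 is the namespace root; each later term draws 1–2 parents from
    earlier terms that still have spare fan-out capacity (at most
    ``max_fanout`` children each), with is_a edges four times as likely
    as part_of.
    """
    rng = spec._rng(1)
    edges: list[tuple[str, str, str]] = []
    fanout = {0: 0}
    for i in range(1, spec.n_terms):
        open_parents = [p for p, c in fanout.items() if c < spec.max_fanout]
        if not open_parents:
            open_parents = list(fanout)
        k = min(int(rng.integers(1, 3)), len(open_parents))
        parents = rng.choice(len(open_parents), size=k, replace=False)
        for idx in sorted(parents):
            p = open_parents[int(idx)]
            rel = "is_a" if rng.random() < 0.8 else "part_of"
            edges.append((_term_id(i), _term_id(p), rel))
            fanout[p] += 1
        fanout[i] = 0

    terms = [
        GOTerm(
            id=_term_id(i),
            name="root" if i == 0 else f"toy term {i}",
            namespace=spec.namespace,
        )
        for i in range(spec.n_terms)
    ]
    graph = OntologyGraph.from_edges(terms, edges)
    if path is not None:
        Path(path).write_text(graph.to_obo())
    return graph


def _gene_id(i: int) -> str:
    return f"g{i + 1:05d}"


def make_annotations(
    spec: FixtureSpec,
    graph: OntologyGraph,
    path: str | Path | None = None,
    format: str = "tsv",
) -> AnnotationSet:
    """Annotate each gene to 1+ random non-root terms; optionally write
    the pairs as a two-column TSV or a GAF 2.2 file."""
    rng = spec._rng(2)
    root = graph.root(spec.namespace)
    candidates = sorted(t for t in graph.terms if t != root)
    lo, hi = spec.annotations_per_gene
    ann = AnnotationSet()
    for i in range(spec.n_genes):
        k = min(int(rng.integers(lo, hi + 1)), len(candidates))
        picks = rng.choice(len(candidates), size=k, replace=False)
        ann.direct[_gene_id(i)] = {candidates[int(j)] for j in sorted(picks)}
    if path is not None:
        Path(path).write_text(annotations_to_text(ann, spec.namespace, format))
    return ann


def annotations_to_text(ann: AnnotationSet, namespace: str, format: str) -> str:
    if format == "tsv":
        lines = ["# gene_id\tgo_id"]
        for gene in sorted(ann.direct):
            for go in sorted(ann.direct[gene]):
                lines.append(f"{gene}\t{go}")
        return "\n".join(lines) + "\n"
    if format == "gaf":
        lines = ["!gaf-version: 2.2"]
        aspect = _NS_ASPECT[namespace]
        for gene in sorted(ann.direct):
            for go in sorted(ann.direct[gene]):
                cols = [
                    "FIX", gene, gene, "", go, "FIX:0000001", "IEA", "",
                    aspect, f"toy gene {gene}", "", "protein",
                    "taxon:1", "20130311", "FIX", "", "",
                ]
                lines.append("\t".join(cols))
        return "\n".join(lines) + "\n"
    raise ConfigError(f"unknown annotation format {format!r}")


def make_gene_id_table(
    spec: FixtureSpec,
    path: str | Path | None = None,
    class_counts: Mapping[str, int] | None = None,
) -> list[tuple[str, str]]:
    """Gene-ID table rows (gene_id, name_class) for the genome-size
    estimator. Default class counts put the ordered-locus class on top,
    mirroring a typical bacterial UniProt extract, with mild seed jitter."""
    rng = spec._rng(4)
    if class_counts is None:
        base = spec.n_genes
        class_counts = {
            "ordered-locus": base + int(rng.integers(0, base // 4 + 1)),
            "Primary": int(base * 0.6) + int(rng.integers(0, base // 10 + 1)),
            "Synonym": int(base * 0.2) + int(rng.integers(0, base // 10 + 1)),
            "ORF": int(base * 0.05) + int(rng.integers(0, base // 20 + 1)),
        }
    rows = []
    for cls in sorted(class_counts):
        for i in range(class_counts[cls]):
            rows.append((f"{cls.lower()}_{i + 1:05d}", cls))
    if path is not None:
        Path(path).write_text(
            "# gene_id\tname_class\n"
            + "\n".join(f"{g}\t{c}" for g, c in rows)
            + "\n"
        )
    return rows


def make_samples(
    spec: FixtureSpec,
    ann: AnnotationSet,
    graph: OntologyGraph,
    outdir: str | Path | None = None,
) -> list[Sample]:
    """Draw one gene list per entry of ``sample_sizes``, without replacement.

    With an ``effect`` map, the first sample is the unweighted baseline
    and later samples oversample genes in the propagated gene set of
    each effect term, with sampling weight multiplied by the term's
    enrichment factor.
    """
    rng = spec._rng(3)
    pool = sorted(ann.direct)
    if any(s > len(pool) for s in spec.sample_sizes):
        raise ConfigError(
            f"sample size exceeds gene pool of {len(pool)} annotated genes"
        )
    weights = np.ones(len(pool))
    if spec.effect:
        prop = ann if ann.propagated else propagate(ann, graph)
        index = {g: i for i, g in enumerate(pool)}
        for term, mult in spec.effect.items():
            for g in prop.propagated[term]:
                weights[index[g]] *= mult

    samples = []
    for s_idx, size in enumerate(spec.sample_sizes):
        if spec.effect and s_idx > 0:
            p = weights / weights.sum()
        else:
            p = None
        picks = rng.choice(len(pool), size=size, replace=False, p=p)
        genes = tuple(pool[int(i)] for i in picks)
        sample = Sample(name=f"sample{s_idx + 1}", genes=genes)
        samples.append(sample)
        if outdir is not None:
            out = Path(outdir) / f"{sample.name}.txt"
            out.write_text("\n".join(sample.genes) + "\n")
    return samples


def planted_recovery_rank(
    seed: int,
    n_terms: int = 60,
    n_genes: int = 1500,
    sample_size: int = 500,
    effect: float = 3.0,
    target_share: float = 0.12,
    min_level_terms: int = 10,
) -> tuple[int, int]:
    """Ground-truth recovery trial for the gene-selection report.

    Generates a toy ontology and annotations, plants an enrichment
    multiplier on one mid-frequency term (closure share closest to
    ``target_share``, on a level with at least ``min_level_terms`` terms
    so the ranking is meaningful), draws a baseline and an enriched
    sample of ``sample_size`` genes, and ranks the planted term in the
    selection table at the planted term's level.

    Returns (rank of the planted term by |log rate of change|, number of
    table rows); recovery is successful when the rank falls in the top
    decile.
    """
    from collections import Counter

    from .selection import Scope, selection_table

    base = FixtureSpec(
        seed=seed,
        n_terms=n_terms,
        n_genes=n_genes,
        annotations_per_gene=(1, 4),
        sample_sizes=(sample_size, sample_size),
    )
    graph = make_ontology(base)
    ann = propagate(make_annotations(base, graph), graph)
    root = graph.root(base.namespace)
    levels = graph.assign_levels(base.namespace)
    level_pop = Counter(levels.values())
    candidates = {
        t: len(ann.propagated[t]) / n_genes
        for t in levels
        if t != root and level_pop[levels[t]] >= min_level_terms
    }
    target = min(candidates, key=lambda t: abs(candidates[t] - target_share))
    spec = FixtureSpec(
        seed=seed,
        n_terms=n_terms,
        n_genes=n_genes,
        annotations_per_gene=(1, 4),
        sample_sizes=(sample_size, sample_size),
        effect={target: effect},
    )
    samples = make_samples(spec, ann, graph)
    scope = Scope(kind="level", namespace=base.namespace, level=levels[target])
    table = selection_table(samples, ann, graph, scope)
    rank = next(i for i, row in enumerate(table) if row.term_id == target)
    return rank, len(table)


def make_bundle(spec: FixtureSpec, outdir: str | Path, format: str = "tsv") -> dict:
    """Write a complete fixture bundle (OBO, annotations, gene lists,
    gene-ID table) into a directory; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph = make_ontology(spec, outdir / "ontology.obo")
    ann = make_annotations(spec, graph, outdir / f"annotations.{format}", format)
    make_gene_id_table(spec, outdir / "gene_id_table.tsv")
    samples = make_samples(spec, ann, graph, outdir)
    return {
        "obo": outdir / "ontology.obo",
        "annotations": outdir / f"annotations.{format}",
        "gene_id_table": outdir / "gene_id_table.tsv",
        "samples": [outdir / f"{s.name}.txt" for s in samples],
    }
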