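from __future__ import annotations

import pytest

from comparego.annotation import AnnotationSet, Sample, propagate
from comparego.fixtures import FixtureSpec, make_annotations, make_ontology
from comparego.ontology import GOTerm, OntologyGraph

MF = "molecular_function"

ROOT, A, B = "GO:0000001", "GO:0000002", "GO:0000003"
X, Y, Z, L = "GO:0000002", "GO:0000003", "GO:0000004", "GO:0000005"


def _terms(ids_names):
    return [GOTerm(id=i, name=n, namespace=MF) for i, n in ids_names]


@pytest.fixture
def chain_graph() -> OntologyGraph:
    """root <- A <- B (a 3-term is_a chain)."""
    return OntologyGraph.from_edges(
        _terms([(ROOT, "root"), (A, "A"), (B, "B")]),
        [(A, ROOT, "is_a"), (B, A, "is_a")],
    )


@pytest.fixture
def diamond_graph() -> OntologyGraph:
    """root <- {X, Y} <- Z, plus childless L at level 1."""
    return OntologyGraph.from_edges(
        _terms([(ROOT, "root"), (X, "X"), (Y, "Y"), (Z, "Z"), (L, "L")]),
        [
            (X, ROOT, "is_a"),
            (Y, ROOT, "part_of"),
            (Z, X, "is_a"),
            (Z, Y, "is_a"),
            (L, ROOT, "is_a"),
        ],
    )


@pytest.fixture
def seed7_spec() -> FixtureSpec:
    return FixtureSpec(seed=7, n_terms=50, n_genes=40, annotations_per_gene=(1, 3), sample_sizes=(20, 10))


@pytest.fixture
def seed7_graph(seed7_spec) -> OntologyGraph:
    return make_ontology(seed7_spec)


@pytest.fixture
def seed7_ann(seed7_spec, seed7_graph) -> AnnotationSet:
    return propagate(make_annotations(seed7_spec, seed7_graph), seed7_graph)


def make_sample(name: str, genes) -> Sample:
    return Sample(name=name, genes=tuple(genes))
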