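"""Expected counts, normalization, two-sample tests, goodness of fit."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats as sps

import oracles
from comparego.annotation import ReferenceGenome, Sample, propagate
from comparego.errors import StatsError
from comparego.selection import GODistribution, Scope, distribution
from comparego.stats import (
    compare_samples,
    expected_counts,
    goodness_of_fit,
    normalization_coefficients,
    percentage_distribution,
)

from conftest import MF


def _ref(K: dict[str, int], N: int) -> ReferenceGenome:
    return ReferenceGenome(per_go_counts=K, genome_size=N, size_source="user_supplied")


def _dist(counts, name="s", units="raw", n_annotated=0, scope=None):
    return GODistribution(
        scope=scope or Scope(kind="leaves", namespace=MF),
        counts=dict(counts),
        units=units,
        sample_name=name,
        n_annotated=n_annotated,
    )


# -- hypergeometric expected counts --------------------------------------


def test_expected_counts_whole_genome_sample():
    ref = _ref({"GO:0000001": 7, "GO:0000002": 3}, N=10)
    exp = expected_counts(ref, 10, ["GO:0000001", "GO:0000002"])
    assert exp.expected == {"GO:0000001": 7.0, "GO:0000002": 3.0}


def test_expected_counts_formula_vs_pmf_enumeration():
    ref = _ref({"GO:0000001": 200}, N=2000)
    exp = expected_counts(ref, 50, ["GO:0000001"])
    assert exp.expected["GO:0000001"] == pytest.approx(5.0, abs=1e-12)
    assert exp.expected["GO:0000001"] == pytest.approx(
        oracles.hypergeom_mean(50, 200, 2000), abs=1e-9
    )


def test_expected_counts_edge_cases():
    ref = _ref({"GO:0000001": 0}, N=100)
    assert expected_counts(ref, 10, ["GO:0000001"]).expected["GO:0000001"] == 0.0
    with pytest.raises(StatsError):
        expected_counts(ref, 101, ["GO:0000001"])
    with pytest.raises(StatsError):
        expected_counts(_ref({}, N=0), 0, [])


# -- normalization -------------------------------------------------------


def _samples(sizes):
    return [
        Sample(name=f"s{i}", genes=tuple(f"s{i}g{j}" for j in range(sz)))
        for i, sz in enumerate(sizes)
    ]


def test_normalization_coefficients_basic():
    plan = normalization_coefficients(_samples([100, 50, 25]))
    assert plan.ordering == ("s0", "s1", "s2")
    assert plan.coefficients == {"s0": 1.0, "s1": 2.0, "s2": 4.0}


def test_normalization_biggest_sample_gets_one_and_product_constant():
    samples = _samples([73, 10, 31])
    plan = normalization_coefficients(samples)
    biggest = plan.ordering[0]
    assert plan.coefficients[biggest] == 1.0
    for s in samples:
        assert plan.coefficients[s.name] * s.size == pytest.approx(73)


def test_normalization_equal_sizes_all_one():
    plan = normalization_coefficients(_samples([40, 40, 40]))
    assert set(plan.coefficients.values()) == {1.0}


def test_normalization_preserves_proportions():
    """Two samples with identical per-GO proportions but different sizes
    end up with equal normalized counts."""
    big = {"GO:0000001": 50.0, "GO:0000002": 30.0}
    small = {t: c / 2 for t, c in big.items()}
    samples = _samples([200, 100])
    plan = normalization_coefficients(samples)
    for t in big:
        assert plan.coefficients["s1"] * small[t] == pytest.approx(
            plan.coefficients["s0"] * big[t]
        )


def test_normalization_rejects_empty_sample():
    with pytest.raises(StatsError):
        normalization_coefficients([])


# -- two-sample tests ----------------------------------------------------


def test_identical_distributions_ks():
    d = _dist({"GO:0000001": 4, "GO:0000002": 9, "GO:0000003": 2})
    res = compare_samples(d, d, "ks_two_sample")
    assert res.statistic == 0.0
    assert res.p_value == 1.0
    assert res.n_categories == 3


def test_ks_matches_independent_oracle():
    a, b = [1, 2, 3, 4], [10, 20, 30, 40]
    da = _dist({f"GO:000000{i+1}": v for i, v in enumerate(a)})
    db = _dist({f"GO:000000{i+1}": v for i, v in enumerate(b)})
    res = compare_samples(da, db, "ks_two_sample")
    stat, p = oracles.ks_two_sample([float(x) for x in a], [float(x) for x in b])
    assert res.statistic == pytest.approx(stat, abs=1e-9)
    assert res.p_value == pytest.approx(p, abs=1e-9)


def test_wilcoxon_all_ties_p_one():
    da = _dist({"GO:0000001": 5, "GO:0000002": 5, "GO:0000003": 5})
    db = _dist({"GO:0000001": 5, "GO:0000002": 5, "GO:0000003": 5}, name="t")
    res = compare_samples(da, db, "wilcoxon_rank_sum")
    assert res.p_value == pytest.approx(1.0)


def test_wilcoxon_exact_path_matches_enumeration():
    """Tie-free small vectors take the exact null distribution."""
    terms = ["GO:0000001", "GO:0000002", "GO:0000003"]
    a = [1.5, 3.25, 9.0]
    b = [2.0, 7.5, 11.0]
    res = compare_samples(
        _dist(dict(zip(terms, a))), _dist(dict(zip(terms, b)), name="t"),
        "wilcoxon_rank_sum",
    )
    assert res.p_value == pytest.approx(oracles.wilcoxon_exact_p(a, b), abs=1e-12)


def test_scope_mismatch_and_small_union_rejected():
    d1 = _dist({"GO:0000001": 1, "GO:0000002": 2}, scope=Scope(kind="leaves", namespace=MF))
    d2 = _dist({"GO:0000001": 1, "GO:0000002": 2}, scope=Scope(kind="level", namespace=MF, level=1))
    with pytest.raises(StatsError, match="scope"):
        compare_samples(d1, d2, "ks_two_sample")
    tiny = _dist({"GO:0000001": 1})
    with pytest.raises(StatsError, match="categories"):
        compare_samples(tiny, tiny, "ks_two_sample")


@pytest.mark.parametrize("test", ["ks_two_sample", "wilcoxon_rank_sum"])
def test_statistic_fidelity_on_random_vectors(test):
    """Statistics and p-values match the independent oracle to 1e-9 on
    random count-vector pairs."""
    rng = np.random.default_rng(42)
    for _ in range(30):
        k = int(rng.integers(5, 25))
        a = rng.integers(0, 40, size=k).astype(float)
        b = rng.integers(0, 40, size=k).astype(float)
        terms = [f"GO:{i + 1:07d}" for i in range(k)]
        res = compare_samples(
            _dist(dict(zip(terms, a))), _dist(dict(zip(terms, b))), test
        )
        if test == "ks_two_sample":
            stat, p = oracles.ks_two_sample(list(a), list(b))
        else:
            stat, p = oracles.wilcoxon(list(a), list(b))
        assert res.statistic == pytest.approx(stat, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-9)


# -- goodness of fit -----------------------------------------------------


def _expdist(expected, n=0, N=1):
    from comparego.stats import ExpectedDistribution

    return ExpectedDistribution(
        expected=dict(expected), n=n, N=N, K={t: 0 for t in expected}
    )


def test_gof_exact_match_gives_zero_statistic():
    obs = _dist({"GO:0000001": 10, "GO:0000002": 20})
    exp = _expdist({"GO:0000001": 10.0, "GO:0000002": 20.0})
    res = goodness_of_fit(obs, exp, "chi_square_gof")
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_gof_scale_invariance_of_exact_match():
    obs = _dist({"GO:0000001": 30, "GO:0000002": 60})
    exp = _expdist({"GO:0000001": 1.0, "GO:0000002": 2.0})  # same proportions
    assert goodness_of_fit(obs, exp, "chi_square_gof").statistic == pytest.approx(0.0)


def test_gof_hand_computed_pearson():
    """Observed (10,20,30) against uniform expectation: the expected
    vector rescales to (20,20,20) and the Pearson statistic is
    sum((O-20)^2/20) = 10 on 2 degrees of freedom."""
    obs = _dist({"GO:0000001": 10, "GO:0000002": 20, "GO:0000003": 30})
    exp = _expdist({t: 1 / 3 for t in obs.counts})
    res = goodness_of_fit(obs, exp, "chi_square_gof")
    assert res.statistic == pytest.approx(10.0, abs=1e-12)
    assert res.n_categories == 3  # df = n_categories - 1 = 2
    assert res.p_value == pytest.approx(float(sps.chi2.sf(10.0, 2)), abs=1e-12)


def test_gof_restricted_to_common_terms_and_errors():
    obs = _dist({"GO:0000001": 5, "GO:0000002": 5, "GO:0000009": 3})
    exp = _expdist({"GO:0000001": 4.0, "GO:0000002": 6.0, "GO:0000008": 2.0})
    res = goodness_of_fit(obs, exp, "chi_square_gof")
    assert res.n_categories == 2
    with pytest.raises(StatsError):
        goodness_of_fit(obs, _expdist({"GO:0000001": 0.0, "GO:0000002": 0.0}), "chi_square_gof")
    with pytest.raises(StatsError):
        goodness_of_fit(_dist({"GO:0000001": 1}), exp, "ks_gof")


def test_gof_ks_variant_runs_two_sample_ks():
    obs = _dist({"GO:0000001": 10, "GO:0000002": 20, "GO:0000003": 30})
    exp = _expdist({"GO:0000001": 12.0, "GO:0000002": 19.0, "GO:0000003": 28.0})
    res = goodness_of_fit(obs, exp, "ks_gof")
    stat, p = oracles.ks_two_sample([10, 20, 30], [12.0, 19.0, 28.0])
    assert res.statistic == pytest.approx(stat, abs=1e-9)
    assert res.p_value == pytest.approx(p, abs=1e-9)


# -- percentages ---------------------------------------------------------


def test_percentage_distribution_trivial():
    s = Sample(name="s", genes=("g1",))
    d = _dist({"GO:0000001": 1}, n_annotated=1)
    pct = percentage_distribution(d, s)
    assert pct.counts == {"GO:0000001": 100.0}
    assert pct.units == "percent"


def test_percentage_distribution_half():
    s = Sample(name="s", genes=tuple(f"g{i}" for i in range(10)))
    d = _dist({"GO:0000001": 5}, n_annotated=10)
    assert percentage_distribution(d, s).counts["GO:0000001"] == 50.0


def test_percentage_matches_set_arithmetic_on_fixtures(seed7_graph, seed7_ann):
    genes = sorted(seed7_ann.direct)[:19]
    s = Sample(name="s", genes=tuple(genes))
    scope = Scope(kind="level", namespace=MF, level=1)
    d = distribution(s, seed7_ann, seed7_graph, scope)
    pct = percentage_distribution(d, s)
    annotated = seed7_ann.propagated[seed7_graph.root(MF)] & set(genes)
    for t in d.counts:
        direct = 100.0 * len(seed7_ann.propagated[t] & set(genes)) / len(annotated)
        assert pct.counts[t] == pytest.approx(direct)


def test_metabolic_process_style_shares():
    """Three niches whose gene lists put 53%, 30% and 46% of annotated
    genes under one level-1 process term."""
    from comparego.annotation import AnnotationSet
    from comparego.ontology import GOTerm, OntologyGraph

    root, met, other = "GO:0000001", "GO:0000002", "GO:0000003"
    g = OntologyGraph.from_edges(
        [GOTerm(id=t, name=n, namespace="biological_process")
         for t, n in [(root, "root"), (met, "metabolic process"), (other, "other")]],
        [(met, root, "is_a"), (other, root, "is_a")],
    )
    shares = {"lungs": 53, "blood": 30, "brain": 46}
    scope = Scope(kind="level", namespace="biological_process", level=1)
    for niche, k in shares.items():
        direct = {}
        for i in range(100):
            direct[f"{niche}{i}"] = {met} if i < k else {other}
        ann = propagate(AnnotationSet(direct=direct), g)
        s = Sample(name=niche, genes=tuple(direct))
        pct = percentage_distribution(distribution(s, ann, g, scope), s)
        assert pct.counts[met] == pytest.approx(float(k))
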