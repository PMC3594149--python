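"""Statistics for comparing GO distributions.

Three families of procedures:

* **Hypergeometric expected counts.** For a sample of n genes drawn
  without replacement from a genome of N genes, K_i of which carry GO
  term i, the expected number of term-i genes in the sample is the
  hypergeometric mean E(GO_i) = n * K_i / N.

* **Whole-distribution two-sample tests.** Rather than testing one GO
  group at a time (the per-term Fisher/chi-square approach of most
  enrichment tools), two samples are compared across *all* GO groups at
  once: the per-GO count vectors over the union of terms at a navigation
  scope are treated as the two observation sets of a two-sample
  Kolmogorov–Smirnov or Wilcoxon rank-sum test.

* **Goodness-of-fit against the genome.** One sample's observed per-GO
  counts are tested against the genome-expected counts over the common
  GO groups, via Pearson's chi-square (expected vector rescaled to the
  observed total, df = categories - 1) or a two-sample K–S on the
  observed-vs-expected vectors.

Sample-size normalization assigns coefficient 1 to the largest sample
S_1 and c_i = l_1 / l_i to the others, so normalized counts
(coefficient × raw count) are comparable across samples of different
sizes. Everything here is deterministic; no randomness is used.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import kolmogorov

from .annotation import ReferenceGenome, Sample
from .errors import StatsError

logger = logging.getLogger(__name__)

#: Categories whose rescaled expected count falls below this floor are
#: dropped from the chi-square goodness-of-fit with a warning.
EXPECTED_FLOOR = 1e-9

#: Largest per-vector length for which the exact Wilcoxon null
#: distribution is used (only when the combined data has no ties).
WILCOXON_EXACT_MAX = 25


@dataclass(frozen=True)
class ExpectedDistribution:
    """Per-GO expected counts E(GO_i) = n·K_i/N under the hypergeometric model."""

    expected: dict[str, float]
    n: int
    N: int
    K: dict[str, int]


@dataclass(frozen=True)
class NormalizationPlan:
    """Sample ordering (largest first) and per-sample coefficients c_i = l_1/l_i."""

    ordering: tuple[str, ...]
    coefficients: dict[str, float]


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    n_categories: int
    scope: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise StatsError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def expected_counts(
    ref: ReferenceGenome, n: int, terms: Sequence[str]
) -> ExpectedDistribution:
    """Hypergeometric expected count n·K_t/N for each requested term."""
    N = ref.genome_size
    if N == 0:
        raise StatsError("genome size N is zero")
    if n > N:
        raise StatsError(f"sample size {n} exceeds genome size {N}")
    K = {t: ref.per_go_counts.get(t, 0) for t in terms}
    expected = {t: n * k / N for t, k in K.items()}
    return ExpectedDistribution(expected=expected, n=n, N=N, K=K)


def normalization_coefficients(samples: Sequence[Sample]) -> NormalizationPlan:
    """Coefficients that put samples of different sizes on a common scale.

    Samples are ordered by size descending (ties keep input order); the
    biggest sample S_1 gets coefficient 1 and every other sample gets
    l_1 / l_i, so coefficient × size is constant across samples.
    """
    if not samples:
        raise StatsError("no samples supplied")
    for s in samples:
        if s.size < 1:
            raise StatsError(f"sample {s.name!r} is empty")
    ordered = sorted(samples, key=lambda s: -s.size)
    l1 = ordered[0].size
    coeffs = {s.name: l1 / s.size for s in ordered}
    return NormalizationPlan(
        ordering=tuple(s.name for s in ordered), coefficients=coeffs
    )


# -- two-sample tests ----------------------------------------------------


def _aligned_vectors(distA, distB) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if distA.scope != distB.scope:
        raise StatsError(
            f"navigation scope mismatch: {distA.scope} vs {distB.scope}"
        )
    union = sorted(set(distA.counts) | set(distB.counts))
    if len(union) < 2:
        raise StatsError(f"need at least 2 GO categories, got {len(union)}")
    a = np.array([distA.counts.get(t, 0) for t in union], dtype=float)
    b = np.array([distB.counts.get(t, 0) for t in union], dtype=float)
    return a, b, union


def _ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    d = float(sps.ks_2samp(a, b).statistic)
    m, n = len(a), len(b)
    t = math.sqrt(m * n / (m + n)) * d
    p = min(1.0, float(kolmogorov(t)))
    return d, p


def _wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    combined = np.concatenate([a, b])
    no_ties = len(np.unique(combined)) == len(combined)
    if np.all(combined == combined[0]):
        # all observations identical: no evidence of any shift
        return float(len(a) * len(b) / 2), 1.0
    if no_ties and max(len(a), len(b)) <= WILCOXON_EXACT_MAX:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(res.pvalue)


def compare_samples(distA, distB, test: str) -> ComparisonResult:
    """Compare two samples' GO distributions over all GO groups at once.

    Both distributions must be computed at the same navigation scope.
    The per-GO count vectors over the union of their terms (absent term
    → count 0) are the two observation sets of the chosen test.
    """
    a, b, union = _aligned_vectors(distA, distB)
    if test == "ks_two_sample":
        stat, p = _ks_two_sample(a, b)
    elif test == "wilcoxon_rank_sum":
        stat, p = _wilcoxon_rank_sum(a, b)
    else:
        raise StatsError(f"unknown two-sample test {test!r}")
    return ComparisonResult(
        test=test,
        statistic=stat,
        p_value=p,
        n_categories=len(union),
        scope=str(distA.scope),
    )


# -- goodness of fit -----------------------------------------------------


def goodness_of_fit(observed, expected: ExpectedDistribution, test: str) -> ComparisonResult:
    """Test one sample's GO distribution against its genome expectation.

    Restricted to the GO groups common to sample and reference. For the
    chi-square variant the expected vector is rescaled to sum to the
    observed total (the classical goodness-of-fit requirement) and
    categories with near-zero expectation are dropped; the K–S variant
    runs a two-sample K–S on the observed and (raw) expected vectors.
    """
    common = sorted(set(observed.counts) & set(expected.expected))
    if len(common) < 2:
        raise StatsError(f"need at least 2 common GO groups, got {len(common)}")
    obs = np.array([observed.counts[t] for t in common], dtype=float)
    exp = np.array([expected.expected[t] for t in common], dtype=float)
    if not np.any(exp > 0):
        raise StatsError("all expected counts are zero")

    if test == "chi_square_gof":
        scaled = exp * obs.sum() / exp.sum()
        keep = scaled >= EXPECTED_FLOOR
        if not np.all(keep):
            logger.warning(
                "dropping %d categor(ies) with expected < %g",
                int((~keep).sum()),
                EXPECTED_FLOOR,
            )
            obs, exp = obs[keep], exp[keep]
            if len(obs) < 2:
                raise StatsError("fewer than 2 categories left after floor")
            scaled = exp * obs.sum() / exp.sum()
        stat, p = sps.chisquare(obs, f_exp=scaled)
        n_cat = len(obs)
    elif test == "ks_gof":
        stat, p = _ks_two_sample(obs, exp)
        n_cat = len(common)
    else:
        raise StatsError(f"unknown goodness-of-fit test {test!r}")
    return ComparisonResult(
        test=test,
        statistic=float(stat),
        p_value=float(p),
        n_categories=n_cat,
        scope=str(observed.scope),
    )


def percentage_distribution(dist, sample: Sample):
    """Convert a raw per-GO count distribution to percentages of the
    sample's annotated genes (the pie-chart units).

    The denominator is the number of distinct annotated sample genes in
    the active namespace; percentages across sibling terms may sum above
    100 because one gene can hit several GO groups.
    """
    denom = dist.n_annotated
    if denom == 0:
        raise StatsError(
            f"sample {sample.name!r} has no annotated genes in this namespace"
        )
    pct = {t: 100.0 * c / denom for t, c in dist.counts.items()}
    return dataclasses.replace(dist, counts=pct, units="percent")
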