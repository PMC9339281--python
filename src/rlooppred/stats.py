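"""Exact-test and rank-test machinery for enrichment and feature comparisons.

Covers the statistics used throughout the analysis: Fisher's exact test for
set overlaps and domain/nucleic-acid-binding enrichment, the two-sided
Mann-Whitney U test (with Bonferroni correction) for feature-distribution
shifts between protein sets, per-bin domain-count enrichment, and generic
multiple-testing adjustment.  All tests are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.stats as sps


@dataclass(frozen=True)
class EnrichmentResult:
    """A 2x2 exact-test result: counts, odds ratio and p-values.

    ``odds_ratio`` is the sample odds ratio a*d / (b*c); it is ``inf`` when
    b*c == 0 and a*d > 0, and ``nan`` for the fully degenerate 0/0 case.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    adjusted_p: float = None  # type: ignore[assignment]
    method: str = "fisher"
    correction: str = "none"

    def __post_init__(self):
        if self.adjusted_p is None:
            object.__setattr__(self, "adjusted_p", self.p_value)

    @property
    def table(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class DistributionComparison:
    """A two-sample rank-test result for one feature."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    adjusted_p: float
    direction: int  # sign of median(a) - median(b)


def fisher_exact(a: int, b: int, c: int, d: int,
                 correction: str = "none", n_tests: int = 1) -> EnrichmentResult:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    The p-value sums hypergeometric probabilities of every table with the
    same margins that is as or less probable than the observed one.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValueError(f"negative counts in contingency table: {counts}")
    if sum(counts) == 0:
        raise ValueError("empty contingency table")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    adj = _adjust_single(p, correction, n_tests)
    return EnrichmentResult(a, b, c, d, odds, float(p), adj,
                            method="fisher", correction=correction)


def mannwhitney_compare(values_a: Sequence[float], values_b: Sequence[float],
                        n_comparisons: int = 1,
                        label_a: str = "a", label_b: str = "b",
                        exact_max_n: int = 20) -> DistributionComparison:
    """Two-sided Mann-Whitney U test with Bonferroni adjustment.

    Uses the exact null distribution when both samples are small
    (``n_a + n_b <= exact_max_n``) and the data are tie-free, and the
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(values_a, dtype=float)
    y = np.asarray(values_b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size + y.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    direction = int(np.sign(np.median(x) - np.median(y)))
    adj = min(1.0, n_comparisons * float(res.pvalue))
    return DistributionComparison(label_a, label_b, x.size, y.size,
                                  float(res.statistic), float(res.pvalue),
                                  adj, direction)


def adjust_pvalues(p_values: Sequence[float], method: str = "bh") -> list[float]:
    """Multiple-testing adjustment: ``bonferroni`` (min(1, m*p)) or ``bh``
    (Benjamini-Hochberg step-up with monotonicity enforcement)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return list(np.minimum(1.0, p.size * p))
    if method == "bh":
        return list(sps.false_discovery_control(p, method="bh"))
    raise ValueError(f"unknown adjustment method: {method!r}")


DOMAIN_BINS = ("0", "1", "2", ">=3")


def _bin_domain_counts(counts: Sequence[int]) -> np.ndarray:
    arr = np.asarray(counts, dtype=int)
    binned = np.zeros(4, dtype=int)
    binned[0] = int(np.sum(arr == 0))
    binned[1] = int(np.sum(arr == 1))
    binned[2] = int(np.sum(arr == 2))
    binned[3] = int(np.sum(arr >= 3))
    return binned


def domain_count_classes(set_counts: Mapping[str, int] | Sequence[int],
                         background_counts: Mapping[str, int] | Sequence[int],
                         correction: str = "none") -> dict[str, dict]:
    """Per-bin ({0, 1, 2, >=3} domains) proportions and Fisher enrichment.

    For each bin, the 2x2 table is (set-in-bin, set-not-in-bin,
    background-in-bin, background-not-in-bin); the background is the
    comparison proteome, disjoint from the set for testing purposes.
    """
    set_vals = list(set_counts.values()) if isinstance(set_counts, Mapping) else list(set_counts)
    bg_vals = (list(background_counts.values())
               if isinstance(background_counts, Mapping) else list(background_counts))
    if not set_vals:
        raise ValueError("empty protein set")
    if not bg_vals:
        raise ValueError("empty background")
    sb = _bin_domain_counts(set_vals)
    bb = _bin_domain_counts(bg_vals)
    n_set, n_bg = sb.sum(), bb.sum()
    results: dict[str, dict] = {}
    raw_p = []
    for i, bin_label in enumerate(DOMAIN_BINS):
        res = fisher_exact(int(sb[i]), int(n_set - sb[i]),
                           int(bb[i]), int(n_bg - bb[i]))
        raw_p.append(res.p_value)
        results[bin_label] = {
            "set_proportion": sb[i] / n_set,
            "background_proportion": bb[i] / n_bg,
            "fisher": res,
        }
    if correction != "none":
        adjusted = adjust_pvalues(raw_p, method=correction)
        for bin_label, adj in zip(DOMAIN_BINS, adjusted):
            r = results[bin_label]["fisher"]
            results[bin_label]["fisher"] = EnrichmentResult(
                r.a, r.b, r.c, r.d, r.odds_ratio, r.p_value, float(adj),
                method="fisher", correction=correction)
    return results


def _adjust_single(p: float, correction: str, n_tests: int) -> float:
    if correction == "none":
        return float(p)
    if correction == "bonferroni":
        return min(1.0, n_tests * float(p))
    if correction == "bh":
        raise ValueError("BH adjustment requires the full p-value list; "
                         "use adjust_pvalues")
    raise ValueError(f"unknown correction: {correction!r}")
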