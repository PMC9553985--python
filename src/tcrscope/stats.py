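"""Diversity/clonality indices, public-clonotype sharing, and rank tests.

Conventions
-----------
* Shannon index in nats, H = -sum p ln p.
* Simpson reported in the dominance form sum(p^2); the diversity form
  1 - sum(p^2) is exposed as a derived field.
* Clonality = 1 - H / ln(richness) (normalized Shannon), configurable should a
  different evenness variant be needed.
* Multiplicity correction is Benjamini-Hochberg everywhere except single-cell
  differential expression, which uses Bonferroni (see :mod:`tcrscope.sc`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ArgumentError
from .repertoire import ClonotypeKey, Repertoire


@dataclass
class TestResult:
    statistic: float
    p_value: float
    alternative: str = "two-sided"
    method: str = ""
    p_adjusted: float | None = None


@dataclass
class DiversityReport:
    shannon: float
    simpson: float
    simpson_diversity: float
    clonality: float | None
    richness: int
    subsample_depth: int | None = None


@dataclass
class OverlapResult:
    n_shared: int
    n_a: int
    n_b: int
    fraction_shared: float
    shared_keys: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def _freqs(rep: Repertoire) -> np.ndarray:
    p = rep.frequencies
    if p.size == 0 or p.sum() <= 0:
        raise ArgumentError("diversity indices require a non-empty repertoire")
    return p[p > 0]


def shannon_index(rep: Repertoire) -> float:
    """Shannon-Wiener index in nats over clones with p > 0."""
    p = _freqs(rep)
    return float(-(p * np.log(p)).sum())


def simpson_index(rep: Repertoire) -> float:
    """Simpson dominance, sum of squared clone frequencies."""
    p = _freqs(rep)
    return float((p**2).sum())


def clonality(rep: Repertoire) -> float:
    """1 - H/ln(richness); 0 for a uniform repertoire, -> 1 under dominance."""
    if rep.richness < 2:
        raise ArgumentError("clonality is undefined for richness < 2")
    return 1.0 - shannon_index(rep) / np.log(rep.richness)


def diversity_report(rep: Repertoire, subsample_depth: int | None = None) -> DiversityReport:
    s = simpson_index(rep)
    return DiversityReport(
        shannon=shannon_index(rep),
        simpson=s,
        simpson_diversity=1.0 - s,
        clonality=clonality(rep) if rep.richness >= 2 else None,
        richness=rep.richness,
        subsample_depth=subsample_depth,
    )


# ---------------------------------------------------------------------------
# public sharing
# ---------------------------------------------------------------------------

def public_overlap(rep_a: Repertoire, rep_b: Repertoire, key: ClonotypeKey = "cdr3_v") -> OverlapResult:
    """Exact-match intersection of clonotype keys between two samples."""
    a = set(rep_a.keys(key))
    b = set(rep_b.keys(key))
    if not a or not b:
        raise ArgumentError("public_overlap requires two non-empty repertoires")
    shared = sorted(a & b)
    union = len(a) + len(b) - len(shared)
    return OverlapResult(
        n_shared=len(shared),
        n_a=len(a),
        n_b=len(b),
        fraction_shared=len(shared) / union if union else 0.0,
        shared_keys=shared,
    )


def overlap_matrix(reps: list[Repertoire], key: ClonotypeKey = "cdr3_v") -> np.ndarray:
    """Symmetric matrix of shared-clonotype counts; diagonal = own richness."""
    if len(reps) < 2:
        raise ArgumentError("overlap_matrix requires at least 2 repertoires")
    keysets = [set(r.keys(key)) for r in reps]
    n = len(reps)
    m = np.zeros((n, n), dtype=int)
    for i in range(n):
        m[i, i] = len(keysets[i])
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = len(keysets[i] & keysets[j])
    return m


# ---------------------------------------------------------------------------
# nonparametric tests + multiplicity
# ---------------------------------------------------------------------------

def mann_whitney_u(group_a, group_b, alternative: str = "two-sided") -> TestResult:
    """Rank-sum test; exact enumeration when n_a * n_b <= 400 and there are no
    ties, otherwise the tie-corrected normal approximation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ArgumentError("mann_whitney_u requires non-empty groups")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):  # degenerate: all observations identical
        return TestResult(statistic=a.size * b.size / 2.0, p_value=1.0, alternative=alternative, method="mann-whitney")
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      alternative=alternative, method=f"mann-whitney ({method})")


def wilcoxon_signed_rank(pre_values, post_values, alternative: str = "two-sided") -> TestResult:
    """Paired signed-rank test; zero differences dropped; exact null up to
    n = 20 informative pairs, normal approximation beyond."""
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.size != post.size:
        raise ArgumentError("paired test requires equal-length samples")
    diff = post - pre
    nz = diff[diff != 0]
    if nz.size == 0:  # all pairs tied: degenerate, p = 1 by convention
        return TestResult(statistic=0.0, p_value=1.0, alternative=alternative, method="wilcoxon signed-rank")
    if nz.size < 5:
        raise ArgumentError("need >= 5 non-zero paired differences")
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 20 and not has_ties) else "approx"
    res = sps.wilcoxon(nz, zero_method="wilcox", alternative=alternative, method=method)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      alternative=alternative, method=f"wilcoxon signed-rank ({method})")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * p.size)
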