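"""Shared fixtures and independent statistical oracles.

The oracles here are deliberately implemented from first principles
(math.comb enumeration, explicit pair counting) so they stay independent of
the scipy/sklearn code paths they check.
"""

import math

import numpy as np
import pandas as pd
import pytest

from tcrscope.repertoire import Repertoire


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def hypergeom_pmf_table(row1: int, row2: int, col1: int) -> dict:
    """Exact hypergeometric pmf over the support of a 2x2 table's top-left cell."""
    n = row1 + row2
    lo, hi = max(0, col1 - row2), min(col1, row1)
    denom = math.comb(n, col1)
    return {k: math.comb(row1, k) * math.comb(row2, col1 - k) / denom for k in range(lo, hi + 1)}


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration: sum of tables no more probable
    than the observed one (relative tie gate 1e-7, the standard convention)."""
    pmf = hypergeom_pmf_table(a + b, c + d, a + c)
    gate = pmf[a] * (1 + 1e-7)
    return sum(v for v in pmf.values() if v <= gate)


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher p: upper hypergeometric tail at the observed cell."""
    pmf = hypergeom_pmf_table(a + b, c + d, a + c)
    return sum(v for k, v in pmf.items() if k >= a)


def pair_count_auroc_oracle(y, scores) -> float:
    """AUROC by explicit loops over all (positive, negative) pairs."""
    pos = [s for yi, s in zip(y, scores) if yi == 1]
    neg = [s for yi, s in zip(y, scores) if yi == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def bh_stepup_oracle(pvals) -> list:
    """Textbook BH step-up adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_repertoire(clones, sample_id="sample", **metadata) -> Repertoire:
    """Build a repertoire from {cdr3: count} or (cdr3, v, j, count) tuples."""
    if isinstance(clones, dict):
        rows = [(c, "TRBV9", "TRBJ2-1", n) for c, n in clones.items()]
    else:
        rows = list(clones)
    df = pd.DataFrame(rows, columns=["cdr3aa", "v_gene", "j_gene", "count"])
    return Repertoire(sample_id, df, metadata)


@pytest.fixture
def simple_rep():
    return make_repertoire({"CASSFGQETQYF": 10, "CASSYEQYF": 30})


@pytest.fixture
def rng():
    return np.random.default_rng(0)
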