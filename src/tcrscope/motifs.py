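"""CDR3 k-mer motif enrichment, motif sharing, and rank correlation.

A transparent enrichment statistic over contiguous k-mers of the trimmed CDR3
interior: for each k-mer present in the target repertoire, a one-sided Fisher
exact test compares the number of target vs reference TCRs containing the
motif (each TCR contributes at most once per motif). Retained motifs are those
with BH-adjusted p below ``alpha`` and fold enrichment at least ``min_fold``,
ranked by the number of target TCRs carrying them (ties broken by motif
string for determinism).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ArgumentError, EmptyRepertoireError, InsufficientDataError
from .repertoire import Repertoire
from .stats import TestResult, bh_adjust

logger = logging.getLogger(__name__)


def extract_kmers(cdr3aa: str, k: int = 3, trim: int = 3) -> list[str]:
    """All contiguous k-mers of the CDR3 interior after trimming ``trim``
    residues from each end; empty (and logged) when nothing remains."""
    if k < 2 or trim < 0:
        raise ArgumentError("require k >= 2 and trim >= 0")
    inner = cdr3aa[trim : len(cdr3aa) - trim]
    if len(inner) < k:
        logger.debug("sequence %s too short for k=%d, trim=%d", cdr3aa, k, trim)
        return []
    return [inner[i : i + k] for i in range(len(inner) - k + 1)]


@dataclass
class MotifTable:
    """Retained motifs with counts, fold, p-values and ranks.

    ``table`` columns: motif, n_target, n_reference, fold, p_value,
    p_adjusted, rank (1 = most target TCRs).
    """

    table: pd.DataFrame
    target_sequences: list[str] = field(default_factory=list)
    k: int = 3
    trim: int = 3

    @property
    def motifs(self) -> list[str]:
        return list(self.table["motif"])


def _motif_presence(sequences: list[str], k: int, trim: int) -> dict[str, int]:
    """motif -> number of sequences containing it at least once."""
    counts: dict[str, int] = {}
    for seq in sequences:
        for m in set(extract_kmers(seq, k, trim)):
            counts[m] = counts.get(m, 0) + 1
    return counts


def motif_enrichment(
    target: Repertoire,
    reference: Repertoire,
    k: int = 3,
    trim: int = 3,
    min_fold: float = 2.0,
    alpha: float = 0.05,
) -> MotifTable:
    """One-sided Fisher enrichment of target k-mers against a reference."""
    tseqs = list(dict.fromkeys(target.clonotypes["cdr3aa"]))  # unique, order kept
    rseqs = list(dict.fromkeys(reference.clonotypes["cdr3aa"]))
    if len(rseqs) < 100:
        logger.warning("reference has only %d clonotypes; >= 100 recommended", len(rseqs))
    t_counts = _motif_presence(tseqs, k, trim)
    if not t_counts:
        raise EmptyRepertoireError("no k-mers extracted from target (k/trim too large)")
    r_counts = _motif_presence(rseqs, k, trim)
    n_t, n_r = len(tseqs), len(rseqs)

    motifs = sorted(t_counts)
    rows = []
    for m in motifs:
        a = t_counts[m]
        b = r_counts.get(m, 0)
        _, p = sps.fisher_exact([[a, n_t - a], [b, n_r - b]], alternative="greater")
        fold = ((a + 0.5) / (n_t + 0.5)) / ((b + 0.5) / (n_r + 0.5))
        rows.append((m, a, b, fold, p))
    df = pd.DataFrame(rows, columns=["motif", "n_target", "n_reference", "fold", "p_value"])
    df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
    kept = df[(df["p_adjusted"] < alpha) & (df["fold"] >= min_fold)].copy()
    kept = kept.sort_values(["n_target", "motif"], ascending=[False, True], kind="stable")
    kept["rank"] = np.arange(1, len(kept) + 1)
    return MotifTable(kept.reset_index(drop=True), target_sequences=tseqs, k=k, trim=trim)


@dataclass
class MotifSharing:
    shared_motifs: list[str]
    n_target_a: dict
    n_target_b: dict
    resolved_count_a: int  # target TCRs in A containing any shared motif


def motif_sharing(table_a: MotifTable, table_b: MotifTable) -> MotifSharing:
    """Intersection of retained motifs and the 'resolved public' TCR count."""
    if len(table_a.table) == 0 or len(table_b.table) == 0:
        raise ArgumentError("motif_sharing requires non-empty motif tables")
    shared = sorted(set(table_a.motifs) & set(table_b.motifs))
    na = dict(zip(table_a.table["motif"], table_a.table["n_target"]))
    nb = dict(zip(table_b.table["motif"], table_b.table["n_target"]))
    shared_set = set(shared)
    resolved = sum(
        1
        for seq in table_a.target_sequences
        if shared_set & set(extract_kmers(seq, table_a.k, table_a.trim))
    )
    return MotifSharing(
        shared_motifs=shared,
        n_target_a={m: int(na[m]) for m in shared},
        n_target_b={m: int(nb[m]) for m in shared},
        resolved_count_a=resolved,
    )


def motif_rank_correlation(table_a: MotifTable, table_b: MotifTable) -> TestResult:
    """Spearman correlation of shared-motif ranks between two tables.

    Both rho and rho^2 are informative; rho is the reported statistic and
    rho^2 is stored in the method string for convenience.
    """
    shared = sorted(set(table_a.motifs) & set(table_b.motifs))
    if len(shared) < 5:
        raise InsufficientDataError(f"only {len(shared)} shared motifs (need >= 5)")
    ra = dict(zip(table_a.table["motif"], table_a.table["rank"]))
    rb = dict(zip(table_b.table["motif"], table_b.table["rank"]))
    x = [ra[m] for m in shared]
    y = [rb[m] for m in shared]
    rho, p = sps.spearmanr(x, y)
    return TestResult(
        statistic=float(rho),
        p_value=float(p),
        alternative="two-sided",
        method=f"spearman (rho^2={rho**2:.4f}, n={len(shared)})",
    )
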