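"""Linking predicted TCR specificity to single-cell phenotype.

Operates on a genes x cells expression matrix plus a cell table (cell ID,
cluster label, clonotype link, specificity label). Clustering itself is an
input: the module consumes a cluster column, so ground-truth clusters from the
synthetic generator or externally computed clusters both work.

Tests provided:

* per-cluster enrichment of a specificity label (one-sided Fisher, BH across
  clusters);
* per-gene differential expression between two cell groups (Welch t-test,
  Bonferroni across genes);
* paired pre/post change of the exhausted-cluster fraction per patient
  (Wilcoxon signed-rank, the paired analogue of the rank-sum test);
* a simplified CellPhoneDB-style ligand-receptor permutation test: the score
  of a (ligand, receptor) pair for ordered clusters (A, B) is the mean of the
  ligand's mean expression in A and the receptor's mean in B, compared against
  a cluster-label-shuffled null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ArgumentError, InsufficientDataError, StateError
from .stats import TestResult, bh_adjust, bonferroni_adjust, wilcoxon_signed_rank

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix with an explicit layer tag."""

    values: np.ndarray  # shape (n_genes, n_cells), non-negative
    genes: list
    cells: list
    layer: str = "counts"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ArgumentError(
                f"matrix shape {self.values.shape} != (n_genes={len(self.genes)}, n_cells={len(self.cells)})"
            )
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._cell_index = {c: i for i, c in enumerate(self.cells)}

    def gene_row(self, gene: str) -> np.ndarray:
        if gene not in self._gene_index:
            raise ArgumentError(f"gene {gene!r} not in matrix")
        return self.values[self._gene_index[gene]]

    def cell_positions(self, cell_ids) -> np.ndarray:
        return np.array([self._cell_index[c] for c in cell_ids])


def lognormalize(counts: ExpressionMatrix, scale: float = 10_000.0) -> ExpressionMatrix:
    """Per-cell library-size normalization to ``scale`` followed by ln(1+x).

    Applying it to an already log-normalized layer is a state error, and
    all-zero cells are rejected with their IDs listed.
    """
    if counts.layer != "counts":
        raise StateError(f"lognormalize expects a counts layer, got {counts.layer!r}")
    totals = counts.values.sum(axis=0)
    zero = np.where(totals == 0)[0]
    if zero.size:
        ids = [counts.cells[i] for i in zero]
        raise ArgumentError(f"all-zero cells cannot be normalized: {ids}")
    vals = np.log1p(scale * counts.values / totals)
    return ExpressionMatrix(vals, list(counts.genes), list(counts.cells), layer="lognorm")


# ---------------------------------------------------------------------------
# cluster enrichment
# ---------------------------------------------------------------------------

def _specificity_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Cells eligible for specificity tests: a recovered TCR is required."""
    if "clonotype_key" in cells.columns:
        return cells[cells["clonotype_key"].notna()]
    return cells


def cluster_enrichment(cells: pd.DataFrame, group: str) -> pd.DataFrame:
    """One-sided Fisher enrichment of a specificity label per cluster.

    ``cells`` needs columns ``cluster`` and ``specificity``; cells labeled
    ``"both"`` count toward each group. Returns one row per cluster with the
    2x2 counts, raw p and BH-adjusted p (family = clusters).
    """
    cells = _specificity_cells(cells)
    clusters = sorted(cells["cluster"].unique())
    if len(clusters) < 2:
        raise ArgumentError("cluster_enrichment requires >= 2 clusters")
    is_group = (cells["specificity"] == group) | (cells["specificity"] == "both")
    if not is_group.any():
        raise ArgumentError(f"no cells labeled {group!r}")
    rows = []
    for cl in clusters:
        in_cl = (cells["cluster"] == cl).to_numpy()
        a = int((is_group & in_cl).sum())  # group cells in cluster
        b = int((is_group & ~in_cl).sum())
        c = int((~is_group & in_cl).sum())
        d = int((~is_group & ~in_cl).sum())
        _, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((cl, a, b, c, d, p))
    out = pd.DataFrame(rows, columns=["cluster", "group_in", "group_out", "other_in", "other_out", "p_value"])
    out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def differential_expression(
    matrix: ExpressionMatrix, cells_a, cells_b, min_cells: int = 10
) -> pd.DataFrame:
    """Per-gene Welch t-test between two cell groups on the lognorm layer.

    Returns log2 fold change of group means (pseudocount 1e-9), the t
    statistic, raw p and Bonferroni-adjusted p (family = tested genes).
    """
    if matrix.layer != "lognorm":
        raise StateError("differential_expression expects the lognorm layer")
    ia = matrix.cell_positions(cells_a)
    ib = matrix.cell_positions(cells_b)
    if ia.size < min_cells or ib.size < min_cells:
        raise ArgumentError(f"both groups need >= {min_cells} cells (got {ia.size}, {ib.size})")
    va = matrix.values[:, ia]
    vb = matrix.values[:, ib]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(va, vb, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance genes: no evidence
    t = np.where(np.isnan(t), 0.0, t)
    eps = 1e-9
    lfc = np.log2((va.mean(axis=1) + eps) / (vb.mean(axis=1) + eps))
    return pd.DataFrame(
        {
            "gene": matrix.genes,
            "log2_fc": lfc,
            "t_statistic": t,
            "p_value": p,
            "p_adjusted": bonferroni_adjust(p),
        }
    )


# ---------------------------------------------------------------------------
# exhaustion-fraction change
# ---------------------------------------------------------------------------

def exhaustion_fraction_change(
    cells: pd.DataFrame, phenotype_cluster, group: str, min_pairs: int = 5
) -> tuple[TestResult, pd.DataFrame]:
    """Paired pre/post change of a phenotype-cluster fraction per patient.

    Per patient (``subject`` column, falling back to ``sample_id``) and
    timepoint, the fraction of ``group``-labeled cells sitting in
    ``phenotype_cluster`` is computed; patients with both timepoints enter a
    two-sided Wilcoxon signed-rank test. Patients lacking a timepoint are
    excluded with a logged count.
    """
    cells = _specificity_cells(cells)
    subj_col = "subject" if "subject" in cells.columns else "sample_id"
    sel = cells[(cells["specificity"] == group) | (cells["specificity"] == "both")]
    if sel.empty:
        raise ArgumentError(f"no cells labeled {group!r}")
    frac = (
        sel.assign(in_cluster=(sel["cluster"] == phenotype_cluster))
        .groupby([subj_col, "timepoint"])["in_cluster"]
        .mean()
        .unstack("timepoint")
    )
    complete = frac.dropna(subset=["pre", "post"]) if {"pre", "post"} <= set(frac.columns) else frac.iloc[0:0]
    n_dropped = len(frac) - len(complete)
    if n_dropped:
        logger.info("excluded %d patients lacking a pre or post sample", n_dropped)
    if len(complete) < min_pairs:
        raise InsufficientDataError(f"only {len(complete)} complete pre/post pairs (need >= {min_pairs})")
    res = wilcoxon_signed_rank(complete["pre"].to_numpy(), complete["post"].to_numpy())
    table = complete.reset_index()[[subj_col, "pre", "post"]]
    return res, table


# ---------------------------------------------------------------------------
# ligand-receptor permutation test
# ---------------------------------------------------------------------------

def load_default_lr_pairs() -> pd.DataFrame:
    """Bundled 20-pair ligand-receptor list (ligand, receptor, class)."""
    with resources.files("tcrscope.data").joinpath("lr_pairs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def interaction_test(
    matrix: ExpressionMatrix,
    clusters: pd.Series,
    lr_pairs,
    cluster_pairs=None,
    n_perm: int = 1000,
    min_cells: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """CellPhoneDB-style permutation test for ligand-receptor co-expression.

    For each ordered cluster pair (A, B) with at least ``min_cells`` cells
    each (the larger cluster is subsampled to the smaller, seeded, so cell
    numbers are normalized across phenotypes), the observed score of a
    (ligand, receptor) pair is 0.5 * (mean ligand expression in A + mean
    receptor expression in B). The null shuffles the A/B assignment of the
    pooled cells ``n_perm`` times; p = (1 + #{null >= observed}) / (n_perm+1),
    never zero. Pairs where either mean is 0 are reported non-expressed with
    no p-value. Cluster pairs below ``min_cells`` are skipped with a log entry.
    """
    if matrix.layer != "lognorm":
        raise StateError("interaction_test expects the lognorm layer")
    clusters = pd.Series(clusters)
    rng = np.random.default_rng(seed)
    sizes = clusters.value_counts()
    if cluster_pairs is None:
        labels = sorted(sizes.index)
        cluster_pairs = [(a, b) for a in labels for b in labels if a != b]
    lr_pairs = [tuple(p) for p in (lr_pairs[["ligand", "receptor"]].itertuples(index=False) if isinstance(lr_pairs, pd.DataFrame) else lr_pairs)]

    rows = []
    for ca, cb in cluster_pairs:
        na, nb = int(sizes.get(ca, 0)), int(sizes.get(cb, 0))
        if na < min_cells or nb < min_cells:
            logger.info("skipping (%s, %s): %d/%d cells < %d", ca, cb, na, nb, min_cells)
            continue
        m = min(na, nb)
        ia = matrix.cell_positions(clusters.index[clusters == ca])
        ib = matrix.cell_positions(clusters.index[clusters == cb])
        ia = rng.choice(ia, size=m, replace=False) if na > m else ia
        ib = rng.choice(ib, size=m, replace=False) if nb > m else ib
        pooled = np.concatenate([ia, ib])
        # one permutation-index matrix per cluster pair, reused for all genes
        perm = np.array([rng.permutation(2 * m) for _ in range(n_perm)])
        for lig, rec in lr_pairs:
            vl = matrix.gene_row(lig)[pooled]
            vr = matrix.gene_row(rec)[pooled]
            mean_l = vl[:m].mean()
            mean_r = vr[m:].mean()
            if mean_l == 0.0 or mean_r == 0.0:
                rows.append((lig, rec, ca, cb, np.nan, np.nan, False))
                continue
            obs = 0.5 * (mean_l + mean_r)
            null = 0.5 * (vl[perm[:, :m]].mean(axis=1) + vr[perm[:, m:]].mean(axis=1))
            p = (1.0 + float((null >= obs).sum())) / (n_perm + 1.0)
            rows.append((lig, rec, ca, cb, obs, p, True))
    return pd.DataFrame(
        rows, columns=["ligand", "receptor", "cluster_a", "cluster_b", "score", "p_value", "expressed"]
    )


def interaction_count_foldchange(results_a: pd.DataFrame, results_b: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """log2 fold change of significant-interaction counts per partner cluster.

    Both result tables must come from the same ligand-receptor list; counts
    get a +1 pseudocount, so swapping the inputs negates the values.
    """
    pairs_a = set(zip(results_a["ligand"], results_a["receptor"]))
    pairs_b = set(zip(results_b["ligand"], results_b["receptor"]))
    if pairs_a != pairs_b:
        raise ArgumentError("result tables use different ligand-receptor lists")
    partners = sorted(set(results_a["cluster_b"]) | set(results_b["cluster_b"]))
    rows = []
    for partner in partners:
        na = int(((results_a["cluster_b"] == partner) & (results_a["p_value"] < alpha)).sum())
        nb = int(((results_b["cluster_b"] == partner) & (results_b["p_value"] < alpha)).sum())
        rows.append((partner, na, nb, np.log2((na + 1) / (nb + 1))))
    return pd.DataFrame(rows, columns=["partner", "n_sig_a", "n_sig_b", "log2_fc"])
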