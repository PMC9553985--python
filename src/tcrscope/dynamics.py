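"""Longitudinal clonal dynamics: expansion calling and clonal replacement.

Expansion between a pre- and post-therapy sample is called per clone with a
two-sided Fisher exact test on raw read counts (clone reads vs remaining
reads, pre vs post), Benjamini-Hochberg corrected within the sample pair; an
expanded clone additionally requires its post frequency to exceed its pre
frequency. Clonal replacement is the post-sample mass of clones absent from
the pre sample (equivalently 1 minus the persisting-clone frequency).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ArgumentError
from .repertoire import ClonotypeKey, Repertoire, clonotype_keys
from .stats import bh_adjust


def _count_frame(pre: Repertoire, post: Repertoire, key: ClonotypeKey) -> pd.DataFrame:
    a = pre.clonotypes.groupby(clonotype_keys(pre.clonotypes, key))["count"].sum()
    b = post.clonotypes.groupby(clonotype_keys(post.clonotypes, key))["count"].sum()
    df = pd.DataFrame({"count_pre": a, "count_post": b}).fillna(0).astype(int)
    df.index.name = "clone"
    return df.reset_index()


def expansion_test(pre: Repertoire, post: Repertoire, min_total: int = 2, key: ClonotypeKey = "cdr3_v") -> pd.DataFrame:
    """Per-clone two-sided Fisher exact expansion test with BH correction.

    Clones with fewer than ``min_total`` reads across both timepoints are not
    tested (singletons can never reach significance and inflate the BH
    family; set ``min_total=0`` to test everything). Returns a DataFrame with
    clone key, counts, odds ratio, p values, direction and the expanded flag.
    """
    total_pre, total_post = pre.total_reads, post.total_reads
    if total_pre == 0 or total_post == 0:
        raise ArgumentError("expansion_test requires positive read depth in both samples")
    df = _count_frame(pre, post, key)
    df["total_pre"] = total_pre
    df["total_post"] = total_post
    df = df[df["count_pre"] + df["count_post"] >= min_total].reset_index(drop=True)

    pvals = np.ones(len(df))
    odds = np.full(len(df), np.nan)
    for i, (cp, cq) in enumerate(zip(df["count_pre"], df["count_post"])):
        table = [[cp, total_pre - cp], [cq, total_post - cq]]
        orat, p = sps.fisher_exact(table, alternative="two-sided")
        pvals[i] = p
        odds[i] = orat
    df["odds_ratio"] = odds
    df["p_value"] = pvals
    df["p_adjusted"] = bh_adjust(pvals) if len(df) else pvals
    freq_pre = df["count_pre"] / total_pre
    freq_post = df["count_post"] / total_post
    df["direction"] = np.select([freq_post > freq_pre, freq_post < freq_pre], ["up", "down"], "flat")
    df["expanded"] = (df["p_adjusted"] < 0.05) & (df["direction"] == "up")
    return df


def count_expanded_by_label(er: pd.DataFrame, labels: dict) -> dict:
    """Number of expanded clones per specificity group.

    ``labels`` maps clone key -> group; missing clones count as ``"none"``;
    a ``"both"``-labeled clone counts in both MAA and VIRAL.
    """
    counts = {"MAA": 0, "VIRAL": 0, "none": 0}
    for clone in er.loc[er["expanded"], "clone"]:
        g = labels.get(clone, "none")
        if g == "both":
            counts["MAA"] += 1
            counts["VIRAL"] += 1
        else:
            counts[g] = counts.get(g, 0) + 1
    return counts


def replacement_metrics(pre: Repertoire, post: Repertoire, labels: dict | None = None, key: ClonotypeKey = "cdr3_v") -> dict:
    """Clonal-replacement summary of the post sample.

    Returns replacing_frequency (post mass of clones absent from pre, equal to
    1 - persisting_frequency exactly), n_replacing, replacing_clonality
    (clonality of the replacing set after renormalization; None below 2
    clones), and an optional per-label breakdown of replacing frequency.
    """
    if pre.richness == 0 or post.richness == 0:
        raise ArgumentError("replacement_metrics requires non-empty repertoires")
    pre_keys = set(clonotype_keys(pre.clonotypes, key))
    post_keys = clonotype_keys(post.clonotypes, key)
    replacing_mask = ~post_keys.isin(pre_keys)
    replacing = post.clonotypes[replacing_mask.to_numpy()]
    replacing_frequency = float(replacing["frequency"].sum())
    persisting_frequency = 1.0 - replacing_frequency  # exact complement by construction
    clon = None
    if len(replacing) >= 2:
        p = replacing["frequency"].to_numpy()
        p = p / p.sum()
        h = float(-(p[p > 0] * np.log(p[p > 0])).sum())
        clon = 1.0 - h / np.log(len(p))
    by_label = None
    if labels is not None:
        lab = post_keys[replacing_mask].map(lambda k: labels.get(k, "none"))
        by_label = replacing.groupby(lab.to_numpy())["frequency"].sum().to_dict()
    return {
        "replacing_frequency": replacing_frequency,
        "persisting_frequency": persisting_frequency,
        "n_replacing": int(len(replacing)),
        "replacing_clonality": clon,
        "replacing_frequency_by_label": by_label,
    }
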