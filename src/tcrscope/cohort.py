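"""Cohort-level analyses of predicted specificity labels.

Covers the aggregate-frequency biomarker (summed frequency of clones carrying
a group label per sample) with cross-validated single-feature logistic
regression AUROC, greedy age-matched subsampling, the dominant-clone flag
(any single labeled clone above 1% of the repertoire), and Kaplan-Meier /
log-rank survival comparison. Multivariable proportional-hazards modeling is
out of scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import ArgumentError, MatchingError, StateError
from .repertoire import Repertoire
from .specificity import pair_auroc
from .stats import TestResult


def _labeled_mask(rep: Repertoire, group: str) -> pd.Series:
    df = rep.clonotypes
    if "specificity" not in df.columns:
        raise StateError("repertoire has no specificity labels; run classify_repertoire first")
    # clones labeled "both" belong to each group
    return (df["specificity"] == group) | (df["specificity"] == "both")


def target_frequency(labeled_rep: Repertoire, group: str) -> tuple[float, int]:
    """(summed read frequency, clone count) of clones carrying ``group``."""
    mask = _labeled_mask(labeled_rep, group)
    return float(labeled_rep.clonotypes.loc[mask, "frequency"].sum()), int(mask.sum())


def target_clone_fraction(labeled_rep: Repertoire, group: str) -> float:
    """Fraction of unique clonotypes carrying the group label (the alternative
    reading of per-sample 'abundance'; summed frequency is the default)."""
    mask = _labeled_mask(labeled_rep, group)
    return float(mask.mean())


def dominant_clone_flag(labeled_rep: Repertoire, group: str, threshold: float = 0.01) -> bool:
    """True iff any single labeled clone exceeds ``threshold`` frequency
    (per-clone dominance, not the group sum)."""
    mask = _labeled_mask(labeled_rep, group)
    freqs = labeled_rep.clonotypes.loc[mask, "frequency"]
    return bool((freqs > threshold).any())


# ---------------------------------------------------------------------------
# biomarker AUROC
# ---------------------------------------------------------------------------

def cohort_auroc(table: pd.DataFrame, folds: int = 10, seed: int = 0) -> tuple[float, list[float]]:
    """Cross-validated AUROC of target_frequency for case/control separation.

    ``table`` needs columns ``group`` (case/control) and ``target_frequency``.
    A single-feature logistic regression (tiny ridge only) is fit per
    stratified fold; pooled out-of-fold scores give one AUROC computed by
    exhaustive pair counting.
    """
    y = (table["group"] == "case").to_numpy().astype(int)
    x = table["target_frequency"].to_numpy(dtype=float).reshape(-1, 1)
    n_case, n_ctrl = int(y.sum()), int((1 - y).sum())
    if n_case < folds or n_ctrl < folds:
        raise ArgumentError(f"need >= {folds} cases and controls for {folds}-fold stratification")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    per_fold = []
    for tr, te in skf.split(x, y):
        lr = LogisticRegression(C=1e6, max_iter=1000)
        lr.fit(x[tr], y[tr])
        oof[te] = lr.predict_proba(x[te])[:, 1]
        if len(set(y[te])) == 2:
            per_fold.append(pair_auroc(y[te], oof[te]))
    return pair_auroc(y, oof), per_fold


def age_matched_subsample(table: pd.DataFrame, ratio: int = 2, caliper: float = 5.0, seed: int = 0) -> pd.DataFrame:
    """Greedy nearest-age matching of ``ratio`` controls per case within
    ``caliper`` years, without replacement; ties broken by a seeded shuffle."""
    if table["age"].isna().any():
        raise ArgumentError("age_matched_subsample requires ages on every row")
    rng = np.random.default_rng(seed)
    cases = table[table["group"] == "case"]
    controls = table[table["group"] == "control"].copy()
    controls = controls.iloc[rng.permutation(len(controls))]  # seeded tie-break order
    available = list(controls.index)
    chosen = []
    for ci in cases.index:
        age = table.loc[ci, "age"]
        cand = sorted(available, key=lambda i: abs(controls.loc[i, "age"] - age))
        cand = [i for i in cand if abs(controls.loc[i, "age"] - age) <= caliper][:ratio]
        if len(cand) < ratio:
            raise MatchingError(f"case {table.loc[ci, 'sample_id']}: only {len(cand)} controls within caliper")
        chosen.extend(cand)
        for i in cand:
            available.remove(i)
    matched = pd.concat([cases, controls.loc[chosen]])
    return matched.sort_index()


def median_split(values) -> np.ndarray:
    """Dichotomize a continuous covariate at its median (high = True)."""
    v = np.asarray(values, dtype=float)
    return v > np.median(v)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimator.

    ``records`` needs columns ``time`` (>= 0) and ``event`` (1 = event,
    0 = censored). Returns a step table (time, survival, at_risk).
    """
    if len(records) == 0:
        raise ArgumentError("km_estimate requires at least one record")
    if (records["time"] < 0).any():
        raise ArgumentError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame({"time": surv.index.to_numpy(), "survival": surv.to_numpy(),
                         "at_risk": at_risk.to_numpy()})


def logrank_test(records: pd.DataFrame, stratum_col: str = "stratum") -> TestResult:
    """Two-stratum log-rank chi-square test (two-sided)."""
    strata = records[stratum_col].unique()
    if len(strata) != 2:
        raise ArgumentError(f"logrank_test requires exactly 2 strata, got {len(strata)}")
    a = records[records[stratum_col] == strata[0]]
    b = records[records[stratum_col] == strata[1]]
    if a["event"].sum() < 1 or b["event"].sum() < 1:
        raise ArgumentError("each stratum needs at least one event")
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"])
    return TestResult(statistic=float(res.test_statistic), p_value=float(res.p_value),
                      alternative="two-sided", method="log-rank")
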