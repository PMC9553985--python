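"""In-silico multimer sorting: probabilistic CDR3beta -> epitope classifiers.

For each epitope a binary classifier is trained on pooled epitope-specific
CDR3beta sequences against an equal number of background sequences. The model
is a Laplace-approximate Gaussian-process classifier with a squared-exponential
kernel over BLOSUM62 CDR3 embeddings (:mod:`tcrscope.encoding`); a regularized
kernel-logistic model with the same external contract is used as a fallback if
the GP fit fails numerically. Per-epitope decision thresholds are calibrated
on held-out background scores to a target false-positive rate (default 5%),
and epitope groups (e.g. the melanoma-antigen panel) call a clone positive if
any member model fires, so the group-level FPR exceeds the per-model target.

Kernel hyperparameters default to a deterministic median-pairwise-distance
length-scale; marginal-likelihood optimization is available via
``optimize_hyperparams=True`` (the single length-scale model is insensitive to
it and the fixed heuristic keeps cross-validation fast and reproducible).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics.pairwise import euclidean_distances, rbf_kernel
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .encoding import CDR3Encoder
from .errors import ArgumentError, CalibrationWarning, StateError, TcrscopeError
from .repertoire import Repertoire

logger = logging.getLogger(__name__)

DEFAULT_TARGET_FPR = 0.05

#: melanoma-associated-antigen and viral epitope groups used throughout
MAA_EPITOPES = [
    "MART1_AAGIGILTV",
    "MART1_ELAGIGILTV",
    "MELOE1_TLNDECWPA",
    "TKT_AMFWSVPTV",
    "SEC24A_FLYNLLTRV",
]
VIRAL_EPITOPES = [
    "CMV_IPSINVHHY",
    "CMV_NLVPMVATV",
    "CMV_TPRVTGGGAM",
    "EBV_GLCTLVAML",
    "EBV_YVLDHLIVV",
    "EBV_RAKFKQLL",
    "IAV_GILGFVFTL",
]


def pair_auroc(y_true, scores) -> float:
    """AUROC by exhaustive concordant-pair counting (ties count 1/2)."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ArgumentError("pair_auroc requires both classes")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# training sets
# ---------------------------------------------------------------------------

@dataclass
class TrainingSet:
    """Pooled positives for one epitope plus a balanced background draw."""

    epitope: str
    positives: list  # (cdr3aa, subject_id or None)
    background: list  # cdr3aa
    balanced: bool = True

    def __post_init__(self):
        pos_seqs = {p[0] for p in self.positives}
        overlap = pos_seqs & set(self.background)
        if overlap:
            raise ArgumentError(f"{len(overlap)} sequences in both positives and background")
        if self.balanced and len(self.background) != len(self.positives):
            raise ArgumentError("balanced training set requires |background| == |positives|")

    @property
    def sequences(self) -> list[str]:
        return [p[0] for p in self.positives] + list(self.background)

    @property
    def labels(self) -> np.ndarray:
        return np.array([1] * len(self.positives) + [0] * len(self.background))

    @property
    def subjects(self) -> list:
        return [p[1] for p in self.positives]


def make_training_set(epitope: str, positives, background_pool, seed: int) -> TrainingSet:
    """Draw an equal-size background (seeded, without replacement, disjoint
    from the positives) and build a balanced :class:`TrainingSet`."""
    positives = [(p, None) if isinstance(p, str) else tuple(p) for p in positives]
    pos_seqs = {p[0] for p in positives}
    pool = [s for s in background_pool if s not in pos_seqs]
    if len(pool) < len(positives):
        raise ArgumentError("background pool too small for a balanced draw")
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(len(pool), size=len(positives), replace=False))
    return TrainingSet(epitope, positives, [pool[i] for i in chosen])


def read_training_table(path) -> dict[str, list]:
    """Read an epitope-labeled TCR table (VDJdb-like TSV).

    Accepts columns cdr3aa/CDR3, epitope/Epitope, subject (optional); returns
    epitope -> list of (cdr3aa, subject).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    cdr3_col = cols.get("cdr3aa") or cols.get("cdr3")
    epi_col = cols.get("epitope")
    if cdr3_col is None or epi_col is None:
        raise ArgumentError("training table needs cdr3aa/CDR3 and epitope columns")
    subj_col = cols.get("subject")
    out: dict[str, list] = {}
    for _, row in df.iterrows():
        subj = row[subj_col] if subj_col else None
        out.setdefault(row[epi_col], []).append((row[cdr3_col], subj))
    return out


# ---------------------------------------------------------------------------
# the classifier
# ---------------------------------------------------------------------------

class EpitopeClassifier(ClassifierMixin, BaseEstimator):
    """Kernelized probabilistic CDR3 classifier for one epitope.

    Parameters
    ----------
    epitope : epitope name carried for bookkeeping.
    max_len, trim, n_components : encoder configuration (see
        :class:`~tcrscope.encoding.CDR3Encoder`).
    length_scale : RBF length-scale; ``"median"`` uses the median pairwise
        Euclidean distance between (a deterministic subsample of) training
        encodings.
    optimize_hyperparams : maximize the Laplace marginal likelihood over the
        kernel hyperparameters instead of keeping the heuristic fixed.
    jitter : diagonal stabilizer added when exposing kernel matrices.
    random_state : seed for every internal random draw.

    Fitted attributes end with an underscore: ``classes_``, ``method_``
    (``"gp"`` or ``"kernel-logistic"``), ``length_scale_``, ``threshold_``
    (None until calibrated), ``cv_report_`` (None until cross-validated).
    """

    def __init__(
        self,
        epitope: str = "",
        max_len: int = 22,
        trim: int = 0,
        n_components: int = 8,
        length_scale="median",
        optimize_hyperparams: bool = False,
        jitter: float = 1e-6,
        random_state: int = 0,
    ):
        self.epitope = epitope
        self.max_len = max_len
        self.trim = trim
        self.n_components = n_components
        self.length_scale = length_scale
        self.optimize_hyperparams = optimize_hyperparams
        self.jitter = jitter
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _encoder(self) -> CDR3Encoder:
        return CDR3Encoder(self.max_len, self.trim, self.n_components)

    def _encode(self, sequences) -> np.ndarray:
        return self._encoder().fit(None).transform(sequences)

    def _resolve_length_scale(self, X: np.ndarray) -> float:
        if self.length_scale != "median":
            return float(self.length_scale)
        rng = np.random.default_rng(self.random_state)
        idx = np.arange(len(X)) if len(X) <= 500 else rng.choice(len(X), 500, replace=False)
        d = euclidean_distances(X[idx])
        med = np.median(d[np.triu_indices_from(d, k=1)])
        return float(med) if med > 0 else 1.0

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y):
        """Fit on CDR3 sequences (iterable of str) and binary labels."""
        y = np.asarray(y)
        if set(np.unique(y)) - {0, 1}:
            raise ArgumentError("labels must be binary 0/1")
        Xe = self._encode(list(X))
        self.classes_ = np.array([0, 1])
        self.X_train_ = Xe
        self.length_scale_ = self._resolve_length_scale(Xe)
        kernel = ConstantKernel(1.0) * RBF(self.length_scale_)
        optimizer = "fmin_l_bfgs_b" if self.optimize_hyperparams else None
        gpc = GaussianProcessClassifier(
            kernel=kernel, optimizer=optimizer, random_state=self.random_state
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gpc.fit(Xe, y)
            self._gpc = gpc
            self.method_ = "gp"
        except Exception as exc:  # numerical failure: kernel-logistic fallback
            logger.warning("GP fit failed (%s); falling back to kernel logistic", exc)
            gamma = 1.0 / (2.0 * self.length_scale_**2)
            K = rbf_kernel(Xe, Xe, gamma=gamma)
            lr = LogisticRegression(C=1.0, max_iter=2000)
            lr.fit(K, y)
            self._klr = lr
            self._gamma = gamma
            self.method_ = "kernel-logistic"
        self.threshold_ = None
        self.cv_report_ = None
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "method_"):
            raise StateError("classifier is not fitted")
        Xe = X if isinstance(X, np.ndarray) and X.ndim == 2 else self._encode(list(X))
        if self.method_ == "gp":
            return self._gpc.predict_proba(Xe)
        K = rbf_kernel(Xe, self.X_train_, gamma=self._gamma)
        return self._klr.predict_proba(K)

    def predict(self, X) -> np.ndarray:
        """Positive call: probability strictly greater than the calibrated
        threshold (0.5 when uncalibrated)."""
        t = self.threshold_ if self.threshold_ is not None else 0.5
        return (self.predict_proba(X)[:, 1] > t).astype(int)

    def kernel_matrix(self, sequences) -> np.ndarray:
        """Jittered squared-exponential kernel on encoded sequences."""
        Xe = self._encode(list(sequences))
        ls = self.length_scale_ if hasattr(self, "length_scale_") else self._resolve_length_scale(Xe)
        K = rbf_kernel(Xe, Xe, gamma=1.0 / (2.0 * ls**2))
        return K + self.jitter * np.eye(len(K))


def train_epitope_model(ts: TrainingSet, config: dict | None = None, seed: int = 0) -> EpitopeClassifier:
    """Train a classifier for one epitope from a balanced training set."""
    if len(ts.positives) < 20:
        raise TcrscopeError(f"{ts.epitope}: need >= 20 positives, got {len(ts.positives)}")
    model = EpitopeClassifier(epitope=ts.epitope, random_state=seed, **(config or {}))
    model.fit(ts.sequences, ts.labels)
    return model


def predict_scores(model: EpitopeClassifier, sequences) -> np.ndarray:
    """Positive-class probability per sequence; un-encodable rows get NaN."""
    seqs = list(sequences)
    scores = np.full(len(seqs), np.nan)
    ok, keep = [], []
    for i, s in enumerate(seqs):
        try:
            model._encoder().fit(None).transform([s])
            ok.append(s)
            keep.append(i)
        except ArgumentError as exc:
            logger.info("sequence %r not scored: %s", s, exc)
    if ok:
        scores[keep] = model.predict_proba(ok)[:, 1]
    return scores


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class ROCReport:
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    precision: np.ndarray
    recall: np.ndarray
    average_precision: float
    scheme: str
    fold_scores: list = field(default_factory=list)  # (y_true, scores) per fold


def _folds(ts: TrainingSet, scheme: str, seed: int):
    n = len(ts.sequences)
    y = ts.labels
    if scheme == "kfold20":
        skf = StratifiedKFold(n_splits=20, shuffle=True, random_state=seed)
        yield from ((tr, te) for tr, te in skf.split(np.zeros(n), y))
    elif scheme == "loo":
        yield from ((tr, te) for tr, te in LeaveOneOut().split(np.zeros(n)))
    elif scheme == "leave_one_subject_out":
        subjects = ts.subjects
        if any(s is None for s in subjects):
            raise ArgumentError("leave_one_subject_out requires subject IDs on all positives")
        uniq = sorted(set(subjects))
        # backgrounds get pseudo-subjects round-robin (seeded order) so each
        # fold holds out that subject's positives plus a background share
        rng = np.random.default_rng(seed)
        bg_idx = np.arange(len(ts.positives), n)
        rng.shuffle(bg_idx)
        bg_subject = {int(i): uniq[j % len(uniq)] for j, i in enumerate(bg_idx)}
        all_subject = np.array(
            [subjects[i] if i < len(ts.positives) else bg_subject[i] for i in range(n)], dtype=object
        )
        for s in uniq:
            te = np.where(all_subject == s)[0]
            tr = np.where(all_subject != s)[0]
            yield tr, te
    else:
        raise ArgumentError(f"unknown CV scheme {scheme!r}")


def cross_validate(ts: TrainingSet, config: dict | None = None, scheme: str = "auto", seed: int = 0) -> ROCReport:
    """Cross-validated ROC/PR evaluation with pooled out-of-fold scores.

    ``scheme="auto"`` follows the sample-size rule: leave-one-out when there
    are fewer than 100 positives, 20-fold stratified CV otherwise.
    """
    if scheme == "auto":
        scheme = "loo" if len(ts.positives) < 100 else "kfold20"
    seqs = np.array(ts.sequences, dtype=object)
    y = ts.labels
    oof = np.full(len(y), np.nan)
    fold_scores = []
    for tr, te in _folds(ts, scheme, seed):
        model = EpitopeClassifier(epitope=ts.epitope, random_state=seed, **(config or {}))
        model.fit(list(seqs[tr]), y[tr])
        s = model.predict_proba(list(seqs[te]))[:, 1]
        oof[te] = s
        fold_scores.append((y[te].copy(), s))
    fpr, tpr, _ = roc_curve(y, oof)
    precision, recall, _ = precision_recall_curve(y, oof)
    return ROCReport(
        fpr=fpr,
        tpr=tpr,
        auroc=float(_trapezoid_auc(fpr, tpr)),
        precision=precision,
        recall=recall,
        average_precision=float(average_precision_score(y, oof)),
        scheme=scheme,
        fold_scores=fold_scores,
    )


# ---------------------------------------------------------------------------
# calibration and panels
# ---------------------------------------------------------------------------

def calibrate_threshold(model: EpitopeClassifier, background_scores, target_fpr: float = DEFAULT_TARGET_FPR) -> float:
    """Smallest threshold t with fraction(background > t) <= target_fpr.

    The threshold is stored on the model; a positive call is a score strictly
    greater than t.
    """
    s = np.sort(np.asarray(background_scores, dtype=float))
    n = s.size
    if n < 100:
        logger.warning("calibrating on only %d background scores (>= 100 recommended)", n)
    if n == 0:
        raise ArgumentError("no background scores for calibration")
    if s[0] == s[-1]:
        warnings.warn("degenerate constant background scores", CalibrationWarning)
        t = float(s[-1])
    else:
        k = int(np.floor(target_fpr * n))  # allowed exceedances
        t = float(s[n - k - 1]) if k < n else float(s[0])
    model.threshold_ = t
    return t


@dataclass
class ModelPanel:
    """Named set of calibrated epitope models with group-union labeling."""

    models: dict  # epitope -> EpitopeClassifier
    groups: dict  # group name -> list of epitope names

    def __post_init__(self):
        for g, epis in self.groups.items():
            for e in epis:
                if e not in self.models:
                    raise ArgumentError(f"group {g!r} references unknown epitope {e!r}")

    def require_calibrated(self) -> None:
        bad = [e for e, m in self.models.items() if getattr(m, "threshold_", None) is None]
        if bad:
            raise StateError(f"uncalibrated models in panel: {bad}")

    def save(self, path) -> None:
        joblib.dump({"format": "tcrscope-panel", "version": 1, "groups": self.groups, "models": self.models}, path)

    @classmethod
    def load(cls, path) -> "ModelPanel":
        blob = joblib.load(path)
        if blob.get("format") != "tcrscope-panel":
            raise ArgumentError(f"{path} is not a tcrscope panel archive")
        return cls(models=blob["models"], groups=blob["groups"])


def classify_repertoire(panel: ModelPanel, rep: Repertoire) -> Repertoire:
    """Label every clonotype with per-epitope flags and a group label.

    Scoring keys on the CDR3 amino-acid sequence alone. The group label is
    the union rule: positive for a group if any member model fires; clones
    positive in more than one group are labeled ``"both"`` and belong to each
    group's frequency. Returns a copy of the repertoire with added columns
    ``pred_<epitope>`` (bool) and ``specificity``.
    """
    panel.require_calibrated()
    out = rep.copy()
    df = out.clonotypes
    uniq = list(dict.fromkeys(df["cdr3aa"]))
    flags_by_epitope = {}
    for name, model in panel.models.items():
        s = predict_scores(model, uniq)
        flag = np.where(np.isnan(s), False, s > model.threshold_)
        flags_by_epitope[name] = dict(zip(uniq, flag))
    for name in panel.models:
        df[f"pred_{name}"] = df["cdr3aa"].map(flags_by_epitope[name]).astype(bool)
    group_hits = {}
    for g, epis in panel.groups.items():
        cols = [f"pred_{e}" for e in epis]
        group_hits[g] = df[cols].any(axis=1)
    labels = pd.Series("none", index=df.index, dtype=object)
    names = list(group_hits)
    for g in names:
        labels[group_hits[g]] = g
    if len(names) >= 2:
        n_hits = np.sum([group_hits[g].to_numpy() for g in names], axis=0)
        labels[n_hits >= 2] = "both"
    df["specificity"] = labels
    return out


def estimate_panel_fpr(panel: ModelPanel, group: str, negative_sequences) -> float:
    """Fraction of known-negative sequences flagged by ANY model in a group."""
    negs = list(negative_sequences)
    if not negs:
        raise ArgumentError("estimate_panel_fpr requires negative sequences")
    if len(negs) < 1000:
        logger.warning("only %d negatives (>= 1000 recommended)", len(negs))
    panel.require_calibrated()
    any_flag = np.zeros(len(negs), dtype=bool)
    for e in panel.groups[group]:
        model = panel.models[e]
        s = predict_scores(model, negs)
        any_flag |= np.where(np.isnan(s), False, s > model.threshold_)
    return float(any_flag.mean())
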