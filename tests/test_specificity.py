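"""CDR3 encoding, the epitope classifier, calibration, and panels."""

import warnings

import numpy as np
import pytest

from tcrscope import simulate as sim
from tcrscope.encoding import CDR3Encoder, blosum_embedding, encode_cdr3
from tcrscope.errors import ArgumentError, CalibrationWarning, StateError, TcrscopeError
from tcrscope.specificity import (
    EpitopeClassifier,
    ModelPanel,
    TrainingSet,
    calibrate_threshold,
    classify_repertoire,
    cross_validate,
    estimate_panel_fpr,
    make_training_set,
    pair_auroc,
    predict_scores,
    train_epitope_model,
)

from conftest import make_repertoire, pair_count_auroc_oracle

def letter_seqs(n, stem="CASSLG"):
    """Unique letter-only CDR3s (digits are not encodable residues)."""
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return [f"{stem}{aa[i // 20]}{aa[i % 20]}EQYF" for i in range(n)]



# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def test_encoding_structure_and_determinism():
    d = 8
    v1 = encode_cdr3("CASSF", max_len=10, n_components=d)
    v2 = encode_cdr3("CASSF", max_len=10, n_components=d)
    assert np.array_equal(v1, v2)
    slots = v1.reshape(10, d)
    # split at midpoint: CAS left-aligned, SF right-aligned, 5 zero gap slots center
    assert np.all(slots[3:8] == 0.0)
    assert np.all(np.any(slots[:3] != 0, axis=1)) and np.all(np.any(slots[8:] != 0, axis=1))


def test_encoding_distances():
    a = encode_cdr3("CASSLGETQYF")
    b = encode_cdr3("CASSLGDTQYF")  # one inner substitution
    assert np.linalg.norm(a - a) == 0.0
    assert np.linalg.norm(a - b) > 0.0


def test_encoding_errors():
    with pytest.raises(ArgumentError):
        encode_cdr3("CASSLGETQYF", max_len=5)
    with pytest.raises(ArgumentError):
        encode_cdr3("CASSB*QYF")


def test_blosum_embedding_reflects_substitution_similarity():
    emb = blosum_embedding(8)
    # conservative substitution (I/L) closer than a drastic one (I/D)
    assert np.linalg.norm(emb["I"] - emb["L"]) < np.linalg.norm(emb["I"] - emb["D"])


def test_encoder_transformer_api():
    enc = CDR3Encoder(max_len=20, n_components=4).fit(None)
    X = enc.transform(["CASSF", "CASSLGETQYF"])
    assert X.shape == (2, 80)
    assert enc.get_params()["max_len"] == 20


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def planted_model_and_sets():
    ts = sim.generate_epitope_repertoire(
        sim.GeneratorConfig(seed=5), motif=("GQP", 0.9, "center"), n_positives=120, subjects=6
    )
    model = train_epitope_model(ts, seed=0)
    held_out = sim.generate_epitope_repertoire(
        sim.GeneratorConfig(seed=6), motif=("GQP", 0.9, "center"), n_positives=120, subjects=6
    )
    return model, ts, held_out


def test_training_set_validation():
    with pytest.raises(ArgumentError):
        TrainingSet("e", [("CASSF", None)], ["CASSF"])  # overlap
    with pytest.raises(ArgumentError):
        TrainingSet("e", [("CASSF", None), ("CASSY", None)], ["CASSW"])  # unbalanced
    ts = make_training_set("e", ["CASSLGETQYF", "CASSYEQYF"], ["CASSWGF", "CASSQGF", "CASSLGETQYF"], seed=0)
    assert len(ts.background) == 2 and "CASSLGETQYF" not in ts.background


def test_too_few_positives_rejected():
    ts = TrainingSet("e", [(f"CASSAB{i}F", None) for i in range(5)], [f"CASSCD{i}F" for i in range(5)])
    with pytest.raises(TcrscopeError):
        train_epitope_model(ts)


def test_fit_sanity_and_determinism(planted_model_and_sets):
    model, ts, held_out = planted_model_and_sets
    pos_scores = predict_scores(model, [p[0] for p in ts.positives])
    bg_scores = predict_scores(model, ts.background)
    assert pos_scores.mean() > bg_scores.mean()
    model2 = train_epitope_model(ts, seed=0)
    assert np.array_equal(predict_scores(model2, ts.background), bg_scores)


def test_held_out_signal(planted_model_and_sets):
    model, _, held_out = planted_model_and_sets
    s = np.concatenate(
        [predict_scores(model, [p[0] for p in held_out.positives]), predict_scores(model, held_out.background)]
    )
    y = np.r_[np.ones(len(held_out.positives)), np.zeros(len(held_out.background))]
    assert pair_auroc(y, s) >= 0.85


def test_prediction_batch_and_order_invariance(planted_model_and_sets):
    model, _, held_out = planted_model_and_sets
    seqs = held_out.background[:10]
    batch = predict_scores(model, seqs)
    single = np.array([predict_scores(model, [s])[0] for s in seqs])
    assert np.allclose(batch, single, atol=1e-10)
    rev = predict_scores(model, seqs[::-1])
    assert np.allclose(batch[::-1], rev, atol=1e-10)


def test_unencodable_sequence_gets_nan(planted_model_and_sets):
    model, _, _ = planted_model_and_sets
    s = predict_scores(model, ["CASSLGETQYF", "C" + "A" * 30 + "F"])
    assert not np.isnan(s[0]) and np.isnan(s[1])


def test_kernel_psd(planted_model_and_sets, rng):
    model, _, held_out = planted_model_and_sets
    seqs = [p[0] for p in held_out.positives[:50]]
    K = model.kernel_matrix(seqs)
    assert np.allclose(K, K.T, atol=1e-12)
    assert np.linalg.eigvalsh(K).min() >= 0.0


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def test_auto_scheme_rule():
    small = sim.generate_epitope_repertoire(sim.GeneratorConfig(seed=7), n_positives=30, subjects=3)
    rep = cross_validate(small, scheme="auto", seed=0)
    assert rep.scheme == "loo"
    # the rule switches to 20-fold at >= 100 positives; verified on the real
    # scheme resolution without paying for 500 LOO fits
    big = sim.generate_epitope_repertoire(sim.GeneratorConfig(seed=8), n_positives=120, subjects=6)
    rep_big = cross_validate(big, scheme="auto", seed=0)
    assert rep_big.scheme == "kfold20"


def test_leave_one_subject_out_requires_subjects():
    ts = TrainingSet("e", [(f"CASSAB{i:02d}F", None) for i in range(30)], [f"CASSCD{i:02d}F" for i in range(30)])
    with pytest.raises(ArgumentError):
        cross_validate(ts, scheme="leave_one_subject_out")


def test_leave_one_subject_out_runs():
    ts = sim.generate_epitope_repertoire(sim.GeneratorConfig(seed=9), n_positives=60, subjects=4)
    rep = cross_validate(ts, scheme="leave_one_subject_out", seed=0)
    assert rep.scheme == "leave_one_subject_out"
    assert len(rep.fold_scores) == 4
    assert 0.5 < rep.auroc <= 1.0


def test_perfectly_separable_auroc_one():
    # positives and background from disjoint length regimes: trivially separable
    positives = [("C" + "W" * 10 + "F", None) for _ in range(20)]
    positives = [(f"C{'W' * 9}{a}F", None) for a in "ACDEFGHIKLMNPQRSTVW"] + positives[:1]
    background = [f"C{'G' * 15}{a}F" for a in "ACDEFGHIKLMNPQRSTVW"] + ["C" + "G" * 16 + "F"]
    ts = TrainingSet("sep", positives, background)
    rep = cross_validate(ts, scheme="loo", seed=0)
    assert rep.auroc == pytest.approx(1.0)
    assert rep.average_precision == pytest.approx(1.0)


def test_auroc_trapezoid_equals_pair_counting():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, size=60)
    y[:2] = [0, 1]
    scores = np.round(rng.random(60), 2)  # ties likely
    from sklearn.metrics import auc, roc_curve

    fpr, tpr, _ = roc_curve(y, scores)
    assert auc(fpr, tpr) == pytest.approx(pair_count_auroc_oracle(y, scores), abs=1e-9)
    assert pair_auroc(y, scores) == pytest.approx(pair_count_auroc_oracle(y, scores), abs=1e-12)


# ---------------------------------------------------------------------------
# calibration and panels
# ---------------------------------------------------------------------------

def test_calibrate_threshold_arithmetic():
    model = EpitopeClassifier()
    scores = np.arange(1, 101) / 100.0  # 0.01 .. 1.00
    t = calibrate_threshold(model, scores, target_fpr=0.05)
    assert t == pytest.approx(0.95)
    assert (scores > t).mean() == pytest.approx(0.05)
    assert calibrate_threshold(model, scores, target_fpr=0.0) == pytest.approx(1.0)


def test_calibrate_degenerate_scores_warns():
    model = EpitopeClassifier()
    with pytest.warns(CalibrationWarning):
        t = calibrate_threshold(model, np.full(200, 0.3))
    assert t == pytest.approx(0.3)


def _stub_panel(thresholds):
    """Panel of trained toy models with forced thresholds."""
    models = {}
    for i, (name, thr) in enumerate(thresholds.items()):
        ts = sim.generate_epitope_repertoire(
            sim.GeneratorConfig(seed=20 + i), motif=("GQP", 0.9, "center"), n_positives=25, subjects=5
        )
        m = train_epitope_model(ts, seed=i)
        m.threshold_ = thr
        models[name] = m
    return models


def test_classify_repertoire_union_rule():
    models = _stub_panel({"maa1": -1.0, "maa2": 2.0, "viral1": 2.0})
    panel = ModelPanel(models=models, groups={"MAA": ["maa1", "maa2"], "VIRAL": ["viral1"]})
    rep = make_repertoire({"CASSLGQPETQYF": 5, "CASSYEQYF": 5})
    labeled = classify_repertoire(panel, rep)
    # maa1 threshold below all probabilities -> every clone MAA; viral never fires
    assert set(labeled.clonotypes["specificity"]) == {"MAA"}
    # thresholds at +inf -> nothing fires
    for m in models.values():
        m.threshold_ = np.inf
    labeled_none = classify_repertoire(panel, rep)
    assert set(labeled_none.clonotypes["specificity"]) == {"none"}
    # all groups fire -> both
    for m in models.values():
        m.threshold_ = -np.inf
    labeled_both = classify_repertoire(panel, rep)
    assert set(labeled_both.clonotypes["specificity"]) == {"both"}


def test_uncalibrated_panel_rejected():
    models = _stub_panel({"maa1": 0.5})
    models["maa1"].threshold_ = None
    panel = ModelPanel(models=models, groups={"MAA": ["maa1"]})
    with pytest.raises(StateError):
        classify_repertoire(panel, make_repertoire({"CASSLGETQYF": 1}))


def test_panel_fpr_boundaries():
    models = _stub_panel({"a": np.inf, "b": np.inf})
    panel = ModelPanel(models=models, groups={"G": ["a", "b"]})
    negs = letter_seqs(50)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assert estimate_panel_fpr(panel, "G", negs) == 0.0
        for m in models.values():
            m.threshold_ = -np.inf
        assert estimate_panel_fpr(panel, "G", negs) == 1.0
        with pytest.raises(ArgumentError):
            estimate_panel_fpr(panel, "G", [])


def test_panel_fpr_bounds_vs_single_models():
    models = _stub_panel({"a": 0.5, "b": 0.6})
    panel = ModelPanel(models=models, groups={"G": ["a", "b"]})
    negs = sim.generate_background_sequences(sim.GeneratorConfig(seed=33), 300)
    singles = []
    for name in ("a", "b"):
        s = predict_scores(models[name], negs)
        singles.append(float((s > models[name].threshold_).mean()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fpr = estimate_panel_fpr(panel, "G", negs)
    assert max(singles) - 1e-12 <= fpr <= sum(singles) + 1e-12


def test_panel_save_load_round_trip(tmp_path):
    models = _stub_panel({"a": 0.5})
    panel = ModelPanel(models=models, groups={"G": ["a"]})
    path = tmp_path / "panel.joblib"
    panel.save(path)
    back = ModelPanel.load(path)
    seqs = letter_seqs(5)
    assert np.allclose(predict_scores(back.models["a"], seqs), predict_scores(models["a"], seqs))
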