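"""Risk scores, logistic fitting, ROC/agreement statistics, calibration."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

import vesselcad as vc
from vesselcad.risk_models import (
    ClassError,
    MissingValueWarning,
    RiskScoreModel,
    SeparationWarning,
    mcnemar_test,
)


# --- published scores -------------------------------------------------------


def test_rs_deform_at_standardized_zero():
    # all z-scored inputs at 0 leaves only the intercept -1.098
    expected = 1.0 / (1.0 + math.exp(1.098))
    assert vc.rs_deform(0, 0, 0, 0) == pytest.approx(expected, abs=1e-12)
    assert vc.rs_deform(0, 0, 0, 0) == pytest.approx(0.2501, abs=1e-4)


def test_rs_deform_increases_with_d_ratio():
    lo = vc.rs_deform(0.3, -0.2, 0.1, 0.0)
    hi = vc.rs_deform(0.3, -0.2, 0.1, 1.0)
    assert hi > lo  # positive D_ratio coefficient


def test_rs_deform_logistic_limits():
    assert vc.rs_deform(0, 50, 50, -50) < 1e-6
    assert vc.rs_deform(50, -50, -50, 50) > 1 - 1e-6


def test_rs_deform_imputes_missing_d_ratio():
    with pytest.warns(MissingValueWarning):
        imputed = vc.rs_deform(0.0, 0.0, 0.0, np.nan)
    assert imputed == pytest.approx(vc.rs_deform(0.0, 0.0, 0.0, 1.0))


def test_rs_deform_standardization_reference():
    model = vc.builtin_rs_deform()
    std = RiskScoreModel(
        name=model.name, feature_names=model.feature_names,
        beta0=model.beta0, betas=model.betas,
        standardization={f: (2.0, 4.0) for f in model.feature_names},
    )
    raw = (6.0, 2.0, -2.0, 10.0)
    z = tuple((v - 2.0) / 4.0 for v in raw)
    assert vc.rs_deform(*raw, model=std) == pytest.approx(vc.rs_deform(*z))


def test_rs_tumor_perfect_sphere():
    # linear predictor 1.526 + 7.093 - 9.826 = -1.207
    assert vc.rs_tumor(1.0, 1.0) == pytest.approx(0.2302, abs=1e-4)


def test_rs_tumor_monotonicity_and_limit():
    assert vc.rs_tumor(1.2, 0.5) > vc.rs_tumor(1.2, 0.9)
    assert vc.rs_tumor(5.0, 0.9) > 1 - 1e-6


def test_rs_tumor_rejects_out_of_range():
    with pytest.raises(ValueError):
        vc.rs_tumor(0.5, 0.8)
    with pytest.raises(ValueError):
        vc.rs_tumor(1.2, 1.5)


def test_model_json_round_trip(tmp_path):
    model = vc.builtin_rs_tumor()
    path = tmp_path / "m.json"
    model.to_json(path)
    back = RiskScoreModel.from_json(path)
    assert back.beta0 == model.beta0
    assert back.betas == model.betas
    assert back.feature_names == model.feature_names


# --- Fisher score -----------------------------------------------------------


def test_fisher_score_equal_means_is_zero():
    assert vc.fisher_score([0, 2, 2, 0], [0, 0, 1, 1]) == 0.0


def test_fisher_score_hand_computed():
    values = [0, 1, 2, 3]
    labels = [0, 0, 1, 1]
    assert vc.fisher_score(values, labels) == pytest.approx(8.0)


def test_fisher_score_single_class():
    with pytest.raises(ClassError):
        vc.fisher_score([1, 2], [1, 1])


def test_fisher_score_degenerate_variances():
    assert vc.fisher_score([1, 1, 1, 1], [0, 0, 1, 1]) == 0.0
    assert vc.fisher_score([1, 1, 2, 2], [0, 0, 1, 1]) == math.inf


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    st.floats(-50, 50).filter(lambda a: abs(a) > 1e-3),
    st.floats(-100, 100),
)
def test_fisher_score_affine_invariant(a, b):
    values = np.array([0.0, 1.5, 2.0, 3.5, 4.0, 7.0])
    labels = np.array([0, 0, 0, 1, 1, 1])
    base = vc.fisher_score(values, labels)
    scaled = vc.fisher_score(a * values + b, labels)
    assert scaled == pytest.approx(base, rel=1e-6)


# --- logistic fitting -------------------------------------------------------


def _two_by_two_data():
    # cell counts: (x=1,y=1)=20, (1,0)=10, (0,1)=5, (0,0)=40
    x = np.array([1] * 30 + [0] * 45)
    y = np.array([1] * 20 + [0] * 10 + [1] * 5 + [0] * 40)
    return x.reshape(-1, 1), y


def test_logistic_slope_closed_form():
    X, y = _two_by_two_data()
    model, table = vc.fit_logistic_wald(X, y)
    assert model.betas[0] == pytest.approx(math.log(16), abs=1e-6)
    assert model.beta0 == pytest.approx(math.log(5 / 40), abs=1e-6)
    assert table.loc[1, "odds_ratio"] == pytest.approx(16.0, rel=1e-6)


def test_logistic_separation_warning():
    x = np.linspace(-1, 1, 40).reshape(-1, 1)
    y = (x.ravel() > 0).astype(int)
    with pytest.warns(SeparationWarning):
        vc.fit_logistic_wald(x, y)


def test_logistic_single_class_rejected():
    with pytest.raises(ClassError):
        vc.fit_logistic_wald(np.zeros((10, 1)), np.ones(10))


def test_wald_type_one_error_calibrated():
    """Under the null (y independent of x), Wald p < .05 about 5% of the time."""
    rng = np.random.default_rng(2024)
    rejections = 0
    n_rep = 500
    for _ in range(n_rep):
        x = rng.standard_normal((5000, 1))
        y = rng.integers(0, 2, 5000)
        if y.min() == y.max():  # pragma: no cover
            continue
        _, table = vc.fit_logistic_wald(x, y)
        rejections += table.loc[1, "p"] < 0.05
    assert 0.03 <= rejections / n_rep <= 0.07


# --- ROC / AUC --------------------------------------------------------------


def test_auc_perfect_separation():
    scores = [0.9, 0.8, 0.1, 0.2]
    y = [1, 1, 0, 0]
    report = vc.evaluate_classifier(scores, y)
    assert report.auc == 1.0
    assert report.sensitivity.value == 1.0
    assert report.specificity.value == 1.0


def test_auc_pair_counting_example():
    assert vc.auc_mann_whitney([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75


def test_auc_all_ties():
    auc = vc.auc_mann_whitney([0.5] * 6, [1, 1, 1, 0, 0, 0])
    assert auc == pytest.approx(0.5, abs=1e-12)


def _brute_force_auc(scores, y):
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


@pytest.mark.parametrize("seed", range(20))
def test_auc_equals_exhaustive_pair_counting(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 200))
    scores = rng.integers(0, 12, n).astype(float)  # coarse grid forces ties
    y = rng.integers(0, 2, n)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    got = vc.auc_mann_whitney(scores, y)
    assert got == pytest.approx(_brute_force_auc(scores, y), abs=1e-12)
    assert got == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


def test_youden_ties_take_lower_cutoff():
    scores = np.array([0.1, 0.2, 0.6, 0.7])
    y = np.array([0, 0, 1, 1])
    # any cutoff in (0.2, 0.6] is Youden-optimal; the lowest candidate wins
    assert vc.youden_cutoff(scores, y) == 0.6


def test_evaluation_report_counts_sum(two_vessel_scene):
    rng = np.random.default_rng(0)
    scores = rng.uniform(size=80)
    y = (rng.uniform(size=80) < scores).astype(int)
    rep = vc.evaluate_classifier(scores, y)
    assert sum(rep.confusion.values()) == 80
    assert 0 <= rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1] <= 1


# --- paired comparisons -----------------------------------------------------


def test_identical_classifiers_compare_as_equal():
    rng = np.random.default_rng(1)
    scores = rng.uniform(size=60)
    y = rng.integers(0, 2, 60)
    y[:2] = [0, 1]
    rep = vc.compare_classifiers(scores, scores.copy(), y)
    assert rep.delong_z == 0.0
    assert rep.delong_p == 1.0
    assert rep.mcnemar_p == 1.0
    assert rep.kappa == 1.0


def test_delong_detects_difference():
    rng = np.random.default_rng(5)
    n = 400
    y = rng.integers(0, 2, n)
    good = y + rng.normal(0, 0.4, n)
    noise = rng.uniform(size=n)
    z, p = vc.delong_test(good, noise, y)
    assert p < 0.01


def test_mcnemar_continuity_corrected_formula():
    # b=10, c=2 discordant pairs: chi2 = (|10-2|-1)^2 / 12
    y = np.zeros(40, dtype=int)
    predsA = np.zeros(40, dtype=int)
    predsB = np.zeros(40, dtype=int)
    predsB[:10] = 1   # A correct, B wrong: b=10
    predsA[10:12] = 1  # B correct, A wrong: c=2
    stat, p, b, c = mcnemar_test(predsA, predsB, y, exact=False)
    assert (b, c) == (10, 2)
    assert stat == pytest.approx((abs(10 - 2) - 1) ** 2 / 12, abs=1e-9)
    assert stat == pytest.approx(4.0833, abs=1e-4)


@pytest.mark.parametrize("b,c", [(0, 0), (3, 1), (5, 5), (12, 8), (20, 0)])
def test_mcnemar_exact_equals_binomial_tails(b, c):
    n = b + c + 10
    y = np.zeros(n, dtype=int)
    predsA = np.zeros(n, dtype=int)
    predsB = np.zeros(n, dtype=int)
    predsB[:b] = 1
    predsA[b:b + c] = 1
    _, p, bb, cc = mcnemar_test(predsA, predsB, y)
    assert (bb, cc) == (b, c)
    if b + c == 0:
        assert p == 1.0
    else:
        expected = min(1.0, 2 * stats.binom.cdf(min(b, c), b + c, 0.5))
        assert p == pytest.approx(expected, abs=1e-12)


def test_kappa_worked_example():
    # agreement table a=40, b=5, c=10, d=45 -> kappa 0.70
    a_preds = np.array([1] * 45 + [0] * 55)
    b_preds = np.array([1] * 40 + [0] * 5 + [1] * 10 + [0] * 45)
    assert vc.cohens_kappa(a_preds, b_preds) == pytest.approx(0.70)


def test_wilcoxon_rank_sum_detects_shift():
    rng = np.random.default_rng(3)
    x = np.concatenate([rng.normal(0, 1, 100), rng.normal(2, 1, 100)])
    y = np.array([0] * 100 + [1] * 100)
    _, p = vc.wilcoxon_rank_sum(x, y)
    assert p < 1e-6


# --- calibration and decision curves ----------------------------------------


def test_hosmer_lemeshow_zero_when_perfectly_calibrated():
    probs = np.repeat(np.arange(0.05, 1.0, 0.1), 20)
    y = np.concatenate([
        np.concatenate([np.ones(round(p * 20)), np.zeros(20 - round(p * 20))])
        for p in np.arange(0.05, 1.0, 0.1)
    ]).astype(int)
    stat, p = vc.hosmer_lemeshow(probs, y, n_groups=10)
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0)


def test_hosmer_lemeshow_rejects_few_distinct():
    with pytest.raises(ValueError):
        vc.hosmer_lemeshow(np.full(100, 0.5), np.zeros(100, int), n_groups=10)


def test_well_calibrated_model_passes_hl():
    # probabilities are externally specified (not fitted on the sample), so
    # the null reference is chi-square with n_groups degrees of freedom
    passes = 0
    n_rep = 200
    for seed in range(n_rep):
        rng = np.random.default_rng(seed)
        probs = rng.uniform(0.05, 0.95, 5000)
        y = (rng.uniform(size=5000) < probs).astype(int)
        _, p = vc.hosmer_lemeshow(probs, y, df=10)
        passes += p > 0.05
    assert passes / n_rep >= 0.90


def test_treat_all_net_benefit_closed_form():
    # prevalence 0.25, threshold 0.5 -> 0.25 - 0.75 * 1 = -0.5
    y = np.array([1] * 25 + [0] * 75)
    probs = np.linspace(0.01, 0.99, 100)
    df = vc.net_benefit(probs, y, thresholds=[0.5])
    assert df.loc[0, "treat_all"] == pytest.approx(-0.5)
    assert df.loc[0, "treat_none"] == 0.0


def test_calibration_and_dca_bundle():
    rng = np.random.default_rng(9)
    probs = rng.uniform(0.05, 0.95, 500)
    y = (rng.uniform(size=500) < probs).astype(int)
    out = vc.calibration_and_dca(probs, y)
    assert out["calibration"].shape == (10, 2)
    assert {"threshold", "net_benefit", "treat_all"} <= set(out["dca"].columns)


# --- nomogram ----------------------------------------------------------------


def test_nomogram_dominant_feature_spans_100():
    model = vc.builtin_rs_tumor()
    ranges = {"T_flat": (1.0, 1.6), "T_sphere": (0.4, 1.0)}
    nomo = vc.nomogram_points(model, ranges)
    spans = {
        f: max(nomo.points(f, lo), nomo.points(f, hi))
        for f, (lo, hi) in ranges.items()
    }
    assert max(spans.values()) == pytest.approx(100.0)
    for f, (lo, hi) in ranges.items():
        ref = nomo.refs[f]
        assert nomo.points(f, ref) == 0.0


def test_nomogram_zero_coefficient_feature():
    model = RiskScoreModel("toy", ["a", "b"], 0.0, [2.0, 0.0])
    nomo = vc.nomogram_points(model, {"a": (0, 1), "b": (0, 1)})
    assert nomo.points("b", 0.7) == 0.0


def test_nomogram_probability_round_trip():
    model = vc.builtin_rs_tumor()
    ranges = {"T_flat": (1.0, 1.6), "T_sphere": (0.4, 1.0)}
    nomo = vc.nomogram_points(model, ranges)
    rng = np.random.default_rng(4)
    for _ in range(100):
        flat = rng.uniform(1.0, 1.6)
        sphere = rng.uniform(0.4, 1.0)
        total = nomo.total_points({"T_flat": flat, "T_sphere": sphere})
        direct = vc.rs_tumor(flat, sphere)
        assert nomo.probability_from_points(total) == pytest.approx(
            direct, abs=1e-6
        )


def test_nomogram_degenerate_model_rejected():
    model = RiskScoreModel("toy", ["a"], 0.0, [0.0])
    with pytest.raises(ValueError):
        vc.nomogram_points(model, {"a": (0, 1)})


# --- per-vessel assembly -----------------------------------------------------


def test_vessel_model_feature_composition():
    for artery in ("CA", "CHA", "SMA"):
        assert vc.vessel_model_features(artery) == ["theta_encase_deg",
                                                    "RS_tumor"]
    for vein in ("PV", "SMV"):
        assert vc.vessel_model_features(vein) == [
            "theta_encase_deg", "RS_tumor", "RS_deform"
        ]


def _scored_table(n_per_vessel=150, seed=0):
    rng = np.random.default_rng(seed)
    frames = []
    for vessel in vc.VESSEL_NAMES:
        theta = rng.uniform(0, 360, n_per_vessel)
        rs_t = rng.uniform(0.1, 0.9, n_per_vessel)
        rs_d = rng.uniform(0.1, 0.9, n_per_vessel)
        lp = -3.0 + 0.012 * theta + 1.2 * rs_t + (
            2.0 * rs_d if vessel in vc.VEINS else 0.0
        )
        y = (rng.uniform(size=n_per_vessel) < 1 / (1 + np.exp(-lp))).astype(int)
        frames.append(pd.DataFrame({
            "vessel": vessel, "theta_encase_deg": theta,
            "RS_tumor": rs_t, "RS_deform": rs_d, "involved": y,
        }))
    return pd.concat(frames, ignore_index=True)


def test_fit_vessel_models_composition_and_recovery():
    df = _scored_table()
    models = vc.fit_vessel_models(df)
    assert set(models) == set(vc.VESSEL_NAMES)
    for vessel, (model, table) in models.items():
        assert set(model.feature_names) == set(vc.vessel_model_features(vessel))
        if vessel in vc.VEINS:
            assert "RS_deform" in model.feature_names
        else:
            assert "RS_deform" not in model.feature_names


def test_score_feature_table_appends_probabilities():
    df = _scored_table(n_per_vessel=60, seed=2)
    df["R_std"] = np.random.default_rng(0).uniform(0, 1, len(df))
    df["D_max"] = 1.0
    df["D_std"] = 0.5
    df["D_ratio"] = 1.2
    df["T_flat"] = 1.3
    df["T_sphere"] = 0.7
    models = {v: m for v, (m, _) in vc.fit_vessel_models(df).items()}
    scored = vc.score_feature_table(df, vessel_models=models)
    assert {"RS_deform", "RS_tumor", "involvement_prob"} <= set(scored.columns)
    assert scored["involvement_prob"].between(0, 1).all()


def test_score_feature_table_empty():
    out = vc.score_feature_table(pd.DataFrame())
    assert len(out) == 0
    assert "RS_deform" in out.columns
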