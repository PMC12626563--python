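"""Risk scores, logistic models and the evaluation statistics.

Two published logistic risk scores are shipped as built-in models:

* ``RS_deform`` — vascular deformation score over the centerline features
  ``(R_std, D_max, D_std, D_ratio)`` with coefficients
  beta0 = -1.098, (0.663, -1.086, -0.745, 2.395). Inputs are standardized
  (z-scored) against a reference stored in the model; the built-in ships
  without a reference, i.e. callers supply already-standardized inputs.
* ``RS_tumor`` — tumor-shape score over ``(T_flat, T_sphere)`` with
  coefficients beta0 = 1.526, (7.093, -9.826), evaluated on the natural
  feature scales.

Around them sit the statistical toolkit used to build and compare per-vessel
involvement models: Fisher-score feature ranking, maximum-likelihood logistic
fits with Wald inference, ROC evaluation with DeLong confidence intervals and
paired tests, McNemar and Cohen's kappa comparisons, Hosmer-Lemeshow
calibration, decision-curve net benefit, and nomogram point tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .mask_io import VEINS, VESSEL_NAMES

#: |coefficient| beyond which a logistic fit is flagged as separated
SEPARATION_BETA = 15.0


class ClassError(ValueError):
    """Binary labels do not contain both classes."""


class ConvergenceError(RuntimeError):
    """Iteratively reweighted least squares failed to converge."""


class SeparationWarning(UserWarning):
    """The fitted logistic model shows signs of complete separation."""


class MissingValueWarning(UserWarning):
    """An undefined feature value was imputed at modeling time."""


def _expit(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


# ---------------------------------------------------------------------------
# model container and built-ins


@dataclass
class RiskScoreModel:
    """A logistic coefficient set with optional input standardization."""

    name: str
    feature_names: list[str]
    beta0: float
    betas: list[float]
    standardization: Optional[dict[str, tuple[float, float]]] = None
    vessel_class: Optional[str] = None  # artery | vein

    def __post_init__(self) -> None:
        if len(self.betas) != len(self.feature_names):
            raise ValueError("betas and feature_names must align")
        if self.standardization:
            for f, (_, sd) in self.standardization.items():
                if sd <= 0:
                    raise ValueError(f"standardization sd for {f} must be > 0")

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Apply the stored (mean, sd) reference column-wise, if any."""
        X = np.asarray(X, dtype=float)
        if not self.standardization:
            return X
        Z = X.copy()
        for j, f in enumerate(self.feature_names):
            if f in self.standardization:
                mean, sd = self.standardization[f]
                Z[..., j] = (Z[..., j] - mean) / sd
        return Z

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        Z = self.transform(np.atleast_2d(X))
        return self.beta0 + Z @ np.asarray(self.betas, dtype=float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _expit(self.linear_predictor(X))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "feature_names": self.feature_names,
            "beta0": self.beta0,
            "betas": self.betas,
            "standardization": (
                {f: {"mean": m, "sd": s}
                 for f, (m, s) in self.standardization.items()}
                if self.standardization else None
            ),
            "vessel_class": self.vessel_class,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "RiskScoreModel":
        std = d.get("standardization")
        if std:
            std = {f: (v["mean"], v["sd"]) for f, v in std.items()}
        return cls(
            name=d["name"], feature_names=list(d["feature_names"]),
            beta0=float(d["beta0"]), betas=[float(b) for b in d["betas"]],
            standardization=std, vessel_class=d.get("vessel_class"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskScoreModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _builtin_specs() -> dict:
    text = (
        resources.files("vesselcad") / "models" / "builtin_models.json"
    ).read_text()
    return json.loads(text)


def builtin_rs_deform() -> RiskScoreModel:
    """The published vascular-deformation risk score (standardized inputs)."""
    return RiskScoreModel.from_dict(_builtin_specs()["RS_deform"])


def builtin_rs_tumor() -> RiskScoreModel:
    """The published tumor-shape risk score (raw-scale inputs)."""
    return RiskScoreModel.from_dict(_builtin_specs()["RS_tumor"])


# ---------------------------------------------------------------------------
# the two published scores


def rs_deform(
    R_std, D_max, D_std, D_ratio, model: Optional[RiskScoreModel] = None
):
    """Vascular deformation risk score in (0, 1).

    Inputs follow the model's standardization metadata (the built-in expects
    z-scored features). An undefined ``D_ratio`` (None/NaN) is imputed with
    the neutral ratio 1.0 before standardization, with a warning.
    """
    model = model or builtin_rs_deform()
    cols = np.broadcast_arrays(*(
        np.array(v, dtype=float) for v in (R_std, D_max, D_std, D_ratio)
    ))
    X = np.stack(cols, axis=-1).astype(float)
    dr = X[..., 3]
    if np.isnan(dr).any():
        warnings.warn(
            "undefined D_ratio imputed as 1.0", MissingValueWarning,
            stacklevel=2,
        )
        X[..., 3] = np.where(np.isnan(dr), 1.0, dr)
    if not np.isfinite(X).all():
        raise ValueError("risk-score inputs must be finite")
    out = _expit(model.linear_predictor(X))
    return float(out[0]) if out.size == 1 else out.reshape(np.shape(cols[0]))


def rs_tumor(T_flat, T_sphere, model: Optional[RiskScoreModel] = None):
    """Tumor-shape risk score in (0, 1); raw feature scales.

    ``T_flat`` must be >= 1 (major/medium axis ratio) and ``T_sphere`` in
    (0, 1] up to the mesh tolerance 0.02.
    """
    model = model or builtin_rs_tumor()
    flat = np.asarray(T_flat, dtype=float)
    sphere = np.asarray(T_sphere, dtype=float)
    if not (np.isfinite(flat).all() and np.isfinite(sphere).all()):
        raise ValueError("risk-score inputs must be finite")
    if (flat < 1.0 - 1e-9).any():
        raise ValueError("T_flat must be >= 1")
    if (sphere <= 0).any() or (sphere > 1.02).any():
        raise ValueError("T_sphere must lie in (0, 1]")
    X = np.stack(np.broadcast_arrays(flat, sphere), axis=-1)
    out = _expit(model.linear_predictor(X))
    return float(out[0]) if out.size == 1 else out.reshape(np.shape(flat))


# ---------------------------------------------------------------------------
# feature selection


def fisher_score(values: Sequence[float], labels: Sequence[int]) -> float:
    """Two-class Fisher score ``(mu1 - mu0)^2 / (var1 + var0)``.

    Population variances; zero when both variances vanish with equal means,
    +inf when they vanish with different means.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ClassError("labels must contain both classes")
    x0, x1 = x[y == 0], x[y == 1]
    num = (x1.mean() - x0.mean()) ** 2
    den = x1.var(ddof=0) + x0.var(ddof=0)
    if den == 0:
        return 0.0 if num == 0 else float("inf")
    return float(num / den)


def rank_features_fisher(
    df: pd.DataFrame, feature_cols: Sequence[str], labels: Sequence[int],
    top_k: Optional[int] = None,
) -> list[tuple[str, float]]:
    """Features sorted by decreasing Fisher score (name tie-break)."""
    scored = sorted(
        ((c, fisher_score(df[c].to_numpy(), labels)) for c in feature_cols),
        key=lambda t: (-t[1], t[0]),
    )
    return scored[:top_k] if top_k else scored


# ---------------------------------------------------------------------------
# logistic fitting


def fit_logistic_wald(
    X: np.ndarray,
    y: Sequence[int],
    feature_names: Optional[Sequence[str]] = None,
    name: str = "logistic",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> tuple[RiskScoreModel, pd.DataFrame]:
    """Maximum-likelihood logistic regression with Wald inference.

    Fit by iteratively reweighted least squares; returns the fitted
    coefficient set and a table with per-coefficient standard errors, Wald z,
    p-values and odds ratios with 95% CIs. Apparent complete separation
    (any |beta| > 15) emits a :class:`SeparationWarning` rather than failing.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) == X.shape[1]:
        X = X.T
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ClassError("outcomes must contain both classes")
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need n > number of features + 1")
    names = list(feature_names) if feature_names else [
        f"x{j}" for j in range(X.shape[1])
    ]
    design = sm.add_constant(X, has_constant="add")
    glm = sm.GLM(y, design, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels' own separation chatter
        res = glm.fit(maxiter=maxiter, tol=tol, tol_criterion="deviance")
    if not res.converged:
        raise ConvergenceError(
            f"IRLS did not converge in {maxiter} iterations "
            f"(deviance {res.deviance:.4g})"
        )
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if np.abs(params).max() > SEPARATION_BETA:
        warnings.warn(
            "possible complete separation (|beta| > 15); Wald statistics "
            "are unreliable", SeparationWarning, stacklevel=2,
        )
    z = np.divide(params, bse, out=np.zeros_like(params), where=bse > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame({
        "term": ["intercept"] + names,
        "beta": params,
        "se": bse,
        "wald_z": z,
        "p": p,
        "odds_ratio": np.exp(params),
        "or_ci_low": np.exp(params - 1.96 * bse),
        "or_ci_high": np.exp(params + 1.96 * bse),
    })
    model = RiskScoreModel(
        name=name, feature_names=names,
        beta0=float(params[0]), betas=[float(b) for b in params[1:]],
    )
    return model, table


# ---------------------------------------------------------------------------
# ROC machinery (midranks shared by the AUC estimate and DeLong variance)


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    z = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out

def _delong_placements(scores: np.ndarray, y: np.ndarray):
    """AUC and the positive/negative placement values of one score vector."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() / (m * n)) - (m + 1.0) / (2.0 * n)
    v01 = (tz[:m] - tx) / n          # placement of each positive
    v10 = 1.0 - (tz[m:] - ty) / m    # placement of each negative
    return float(auc), v01, v10


def auc_mann_whitney(scores: Sequence[float], y: Sequence[int]) -> float:
    """AUC as the Mann-Whitney pair statistic (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ClassError("labels must contain both classes")
    auc, _, _ = _delong_placements(scores, y)
    return auc


def delong_ci(scores, y, alpha: float = 0.05) -> tuple[float, float, float]:
    """(AUC, CI low, CI high) via the DeLong variance."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    auc, v01, v10 = _delong_placements(scores, y)
    var = v01.var(ddof=1) / len(v01) + v10.var(ddof=1) / len(v10)
    half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(max(var, 0.0))
    return auc, max(0.0, auc - half), min(1.0, auc + half)


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if n == 0:
        return 0.0, 1.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass
class Proportion:
    value: float
    numerator: int
    denominator: int
    ci: tuple[float, float]


@dataclass
class EvaluationReport:
    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    confusion: dict[str, int]  # tp, fp, fn, tn

    def as_dict(self) -> dict:
        def prop(p: Proportion) -> dict:
            return {"value": p.value, "n": f"{p.numerator}/{p.denominator}",
                    "ci": list(p.ci)}
        return {
            "sensitivity": prop(self.sensitivity),
            "specificity": prop(self.specificity),
            "ppv": prop(self.ppv),
            "npv": prop(self.npv),
            "auc": {"value": self.auc, "ci": list(self.auc_ci)},
            "cutoff": self.cutoff,
            "confusion": dict(self.confusion),
        }


def youden_cutoff(scores: Sequence[float], y: Sequence[int]) -> float:
    """Threshold maximizing sensitivity + specificity - 1 (ties -> lower)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    best_t, best_j = None, -np.inf
    for t in np.unique(scores):  # ascending, so ties keep the lower cutoff
        pred = scores >= t
        sens = (pred & (y == 1)).sum() / max((y == 1).sum(), 1)
        spec = (~pred & (y == 0)).sum() / max((y == 0).sum(), 1)
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t


def evaluate_classifier(
    scores: Sequence[float], y: Sequence[int],
    cutoff: Optional[float] = None,
) -> EvaluationReport:
    """Sens/spec/PPV/NPV at a cutoff (default Youden-optimal) plus ROC AUC.

    Proportion CIs are exact Clopper-Pearson; the AUC CI uses the DeLong
    variance.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ClassError("labels must contain both classes")
    if cutoff is None:
        cutoff = youden_cutoff(scores, y)
    pred = scores >= cutoff
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())

    def prop(k: int, n: int) -> Proportion:
        return Proportion(k / n if n else float("nan"), k, n,
                          _clopper_pearson(k, n))

    auc, lo, hi = delong_ci(scores, y)
    return EvaluationReport(
        sensitivity=prop(tp, tp + fn),
        specificity=prop(tn, tn + fp),
        ppv=prop(tp, tp + fp),
        npv=prop(tn, tn + fn),
        auc=auc, auc_ci=(lo, hi), cutoff=float(cutoff),
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    )


def delong_test(scoresA, scoresB, y) -> tuple[float, float]:
    """Paired DeLong test for equal AUCs: (z, two-sided p)."""
    scoresA = np.asarray(scoresA, dtype=float)
    scoresB = np.asarray(scoresB, dtype=float)
    y = np.asarray(y).astype(int)
    aucA, vA01, vA10 = _delong_placements(scoresA, y)
    aucB, vB01, vB10 = _delong_placements(scoresB, y)
    m, n = len(vA01), len(vA10)
    s01 = np.cov(np.vstack([vA01, vB01]), ddof=1)
    s10 = np.cov(np.vstack([vA10, vB10]), ddof=1)
    cov = s01 / m + s10 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 1e-15:
        return 0.0, 1.0
    z = (aucA - aucB) / np.sqrt(var_diff)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def mcnemar_test(
    predsA, predsB, y, exact: Optional[bool] = None
) -> tuple[float, float, int, int]:
    """McNemar test on paired correctness: (statistic, p, b, c).

    ``b``/``c`` count the discordant pairs (A correct & B wrong, and vice
    versa). By default the exact binomial test is used when b + c < 25 and
    the continuity-corrected chi-square otherwise; pass ``exact`` to force
    either form.
    """
    predsA = np.asarray(predsA).astype(int)
    predsB = np.asarray(predsB).astype(int)
    y = np.asarray(y).astype(int)
    okA = predsA == y
    okB = predsB == y
    b = int((okA & ~okB).sum())
    c = int((~okA & okB).sum())
    a = int((okA & okB).sum())
    d = int((~okA & ~okB).sum())
    table = [[a, b], [c, d]]
    if exact is None:
        exact = (b + c) < 25
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return float(res.statistic), float(min(res.pvalue, 1.0)), b, c


def cohens_kappa(predsA, predsB) -> float:
    """Chance-corrected agreement between two binary raters."""
    a = np.asarray(predsA).astype(int)
    b = np.asarray(predsB).astype(int)
    if a.shape != b.shape:
        raise ValueError("paired predictions must have equal length")
    n = len(a)
    po = (a == b).mean()
    pe = (a.mean() * b.mean()) + ((1 - a.mean()) * (1 - b.mean()))
    if pe == 1.0:
        return 1.0
    return float((po - pe) / (1 - pe))


@dataclass
class ComparisonReport:
    delong_z: float
    delong_p: float
    mcnemar_statistic: float
    mcnemar_p: float
    discordant: tuple[int, int]
    kappa: float


def compare_classifiers(
    scoresA, scoresB, y,
    predsA=None, predsB=None,
) -> ComparisonReport:
    """Paired comparison of two classifiers on the same cases.

    AUCs are compared with the paired DeLong test; binary predictions (by
    default thresholded at each score's Youden cutoff) with McNemar's test
    and Cohen's kappa.
    """
    scoresA = np.asarray(scoresA, dtype=float)
    scoresB = np.asarray(scoresB, dtype=float)
    y = np.asarray(y).astype(int)
    if not (len(scoresA) == len(scoresB) == len(y)):
        raise ValueError("paired comparisons need equal-length inputs")
    if predsA is None:
        predsA = (scoresA >= youden_cutoff(scoresA, y)).astype(int)
    if predsB is None:
        predsB = (scoresB >= youden_cutoff(scoresB, y)).astype(int)
    z, p = delong_test(scoresA, scoresB, y)
    stat, mp, bcount, ccount = mcnemar_test(predsA, predsB, y)
    kappa = cohens_kappa(predsA, predsB)
    return ComparisonReport(z, p, stat, mp, (bcount, ccount), kappa)


def wilcoxon_rank_sum(values, labels) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of a feature between the two classes."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ClassError("labels must contain both classes")
    res = stats.ranksums(x[y == 1], x[y == 0])
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# calibration and decision curves


def hosmer_lemeshow(
    probs, y, n_groups: int = 10, df: Optional[int] = None
) -> tuple[float, float]:
    """Hosmer-Lemeshow goodness-of-fit over equal-count risk groups.

    ``df`` defaults to ``n_groups - 2``, the convention for probabilities
    fitted on the same data; for externally specified probabilities the
    statistic is chi-square with ``n_groups`` degrees of freedom, which the
    caller can request explicitly.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y).astype(int)
    if (probs <= 0).any() or (probs >= 1).any():
        raise ValueError("probabilities must lie strictly in (0, 1)")
    if len(np.unique(probs)) < n_groups:
        raise ValueError(
            f"need at least {n_groups} distinct predicted probabilities"
        )
    order = np.argsort(probs, kind="mergesort")
    stat = 0.0
    for idx in np.array_split(order, n_groups):
        e1 = probs[idx].sum()
        o1 = y[idx].sum()
        e0 = len(idx) - e1
        o0 = len(idx) - o1
        stat += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
    if df is None:
        df = n_groups - 2
    p = float(stats.chi2.sf(stat, df=df))
    return float(stat), p


def calibration_curve_points(probs, y, n_groups: int = 10) -> np.ndarray:
    """(mean predicted, observed rate) per equal-count group; shape (g, 2)."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y).astype(int)
    order = np.argsort(probs, kind="mergesort")
    pts = [
        (probs[idx].mean(), y[idx].mean())
        for idx in np.array_split(order, n_groups)
    ]
    return np.array(pts)


def net_benefit(probs, y, thresholds=None) -> pd.DataFrame:
    """Decision-curve net benefit of the model vs treat-all/treat-none.

    ``NB(t) = TP/n - (FP/n) * t / (1 - t)`` with positives called at
    ``prob >= t``.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    n = len(y)
    prevalence = y.mean()
    rows = []
    for t in thresholds:
        w = t / (1 - t)
        pred = probs >= t
        tp = (pred & (y == 1)).sum()
        fp = (pred & (y == 0)).sum()
        rows.append({
            "threshold": t,
            "net_benefit": tp / n - (fp / n) * w,
            "treat_all": prevalence - (1 - prevalence) * w,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


def calibration_and_dca(
    probs, y, n_groups: int = 10, thresholds=None
) -> dict:
    """Bundle: Hosmer-Lemeshow test, calibration points, net-benefit curve."""
    stat, p = hosmer_lemeshow(probs, y, n_groups)
    return {
        "hl_statistic": stat,
        "hl_p": p,
        "calibration": calibration_curve_points(probs, y, n_groups),
        "dca": net_benefit(probs, y, thresholds),
    }


# ---------------------------------------------------------------------------
# nomogram


@dataclass
class NomogramTable:
    """Point-scale rendering of a logistic model.

    For each feature, the points awarded at value ``v`` are proportional to
    ``|beta| * |v - v_ref|`` with ``v_ref`` the range endpoint minimizing the
    linear predictor; the feature with the largest coefficient-times-range
    spans exactly 100 points. Total points map back to probability through
    the recovered linear predictor.
    """

    model_name: str
    scale: float  # linear-predictor units per 100 points
    lp_min: float  # linear predictor with every feature at its v_ref
    refs: dict[str, float]
    betas: dict[str, float]
    ranges: dict[str, tuple[float, float]]

    def points(self, feature: str, value: float) -> float:
        beta = self.betas[feature]
        return 100.0 * abs(beta) * abs(value - self.refs[feature]) / self.scale

    def total_points(self, values: dict[str, float]) -> float:
        return sum(self.points(f, v) for f, v in values.items())

    def probability_from_points(self, total: float) -> float:
        return float(_expit(self.lp_min + self.scale * total / 100.0))

    def to_dataframe(self, n_points: int = 11) -> pd.DataFrame:
        rows = []
        for f, (lo, hi) in self.ranges.items():
            for v in np.linspace(lo, hi, n_points):
                rows.append({"feature": f, "value": v,
                             "points": self.points(f, v)})
        return pd.DataFrame(rows)


def nomogram_points(
    model: RiskScoreModel, feature_ranges: dict[str, tuple[float, float]]
) -> NomogramTable:
    """Build the nomogram point mapping for a fitted logistic model."""
    scale = 0.0
    refs: dict[str, float] = {}
    betas: dict[str, float] = {}
    for f, beta in zip(model.feature_names, model.betas):
        lo, hi = feature_ranges[f]
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError(f"range for {f} must be finite")
        scale = max(scale, abs(beta) * (hi - lo))
        refs[f] = lo if beta >= 0 else hi  # endpoint minimizing beta * v
        betas[f] = float(beta)
    if scale == 0:
        raise ValueError("degenerate model: all coefficient-range products 0")
    lp_min = model.beta0 + sum(
        betas[f] * refs[f] for f in model.feature_names
    )
    return NomogramTable(
        model_name=model.name, scale=float(scale), lp_min=float(lp_min),
        refs=refs, betas=betas,
        ranges={f: tuple(map(float, feature_ranges[f]))
                for f in model.feature_names},
    )


# ---------------------------------------------------------------------------
# feature-table scoring


def standardization_from_table(
    df: pd.DataFrame, features: Sequence[str]
) -> dict[str, tuple[float, float]]:
    """Per-feature (mean, population sd) reference computed from a table."""
    out = {}
    for f in features:
        x = df[f].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        sd = float(x.std(ddof=0))
        out[f] = (float(x.mean()), sd if sd > 0 else 1.0)
    return out


def score_feature_table(
    df: pd.DataFrame,
    deform_model: Optional[RiskScoreModel] = None,
    tumor_model: Optional[RiskScoreModel] = None,
    vessel_models: Optional[dict[str, RiskScoreModel]] = None,
    vessel_col: str = "vessel",
) -> pd.DataFrame:
    """Append ``RS_deform``/``RS_tumor`` (and involvement probabilities).

    If the deformation model carries no standardization reference, one is
    computed from the table itself (z-scoring against the table's own mean
    and population sd) and used for scoring. With fitted per-vessel models an
    ``involvement_prob`` column is added, using each vessel's own feature
    composition (deformation score for veins only).
    """
    df = df.copy()
    if df.empty:
        for c in ("RS_deform", "RS_tumor"):
            df[c] = pd.Series(dtype=float)
        return df
    deform_model = deform_model or builtin_rs_deform()
    tumor_model = tumor_model or builtin_rs_tumor()
    if deform_model.standardization is None:
        deform_model = RiskScoreModel(
            name=deform_model.name,
            feature_names=deform_model.feature_names,
            beta0=deform_model.beta0, betas=deform_model.betas,
            standardization=standardization_from_table(
                df, deform_model.feature_names),
            vessel_class=deform_model.vessel_class,
        )
    # rows with missing inputs (absent vessels) pass through as NaN scores;
    # an undefined D_ratio on an otherwise complete row is imputed as 1.0
    deform_in = df[["R_std", "D_max", "D_std"]].to_numpy(dtype=float)
    ok_d = np.isfinite(deform_in).all(axis=1)
    rs_d = np.full(len(df), np.nan)
    if ok_d.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", MissingValueWarning)
            rs_d[ok_d] = rs_deform(
                df.loc[ok_d, "R_std"], df.loc[ok_d, "D_max"],
                df.loc[ok_d, "D_std"], df.loc[ok_d, "D_ratio"],
                model=deform_model,
            )
    df["RS_deform"] = rs_d
    tumor_in = df[["T_flat", "T_sphere"]].to_numpy(dtype=float)
    ok_t = np.isfinite(tumor_in).all(axis=1)
    rs_t = np.full(len(df), np.nan)
    if ok_t.any():
        rs_t[ok_t] = rs_tumor(df.loc[ok_t, "T_flat"],
                              df.loc[ok_t, "T_sphere"], model=tumor_model)
    df["RS_tumor"] = rs_t
    if vessel_models:
        probs = np.full(len(df), np.nan)
        for vessel, model in vessel_models.items():
            sel = (df[vessel_col] == vessel).to_numpy()
            if not sel.any():
                continue
            expected = vessel_model_features(vessel)
            if set(model.feature_names) != set(expected):
                raise ValueError(
                    f"{vessel} model features {model.feature_names} != "
                    f"expected {expected}"
                )
            X = df.loc[sel, model.feature_names].to_numpy(dtype=float)
            probs[sel] = model.predict(X)
        df["involvement_prob"] = probs
    return df


# ---------------------------------------------------------------------------
# per-vessel model assembly


def vessel_model_features(vessel: str) -> list[str]:
    """Feature composition of a per-vessel involvement model.

    Every vessel model carries the encasement angle (degrees) and the tumor
    shape score; the deformation score enters for veins only.
    """
    if vessel not in VESSEL_NAMES:
        raise ValueError(f"unknown vessel {vessel!r}")
    feats = ["theta_encase_deg", "RS_tumor"]
    if vessel in VEINS:
        feats.append("RS_deform")
    return feats


def fit_vessel_models(
    df: pd.DataFrame,
    label_col: str = "involved",
    vessel_col: str = "vessel",
) -> dict[str, tuple[RiskScoreModel, pd.DataFrame]]:
    """Fit one involvement model per vessel present in a scored table.

    The table must already carry ``theta_encase_deg``, ``RS_tumor`` and (for
    veins) ``RS_deform`` columns plus binary labels. Vessels whose labels are
    single-class are skipped with a warning.
    """
    out: dict[str, tuple[RiskScoreModel, pd.DataFrame]] = {}
    for vessel in VESSEL_NAMES:
        sub = df[df[vessel_col] == vessel]
        if sub.empty:
            continue
        feats = vessel_model_features(vessel)
        y = sub[label_col].to_numpy().astype(int)
        if len(np.unique(y)) < 2:
            warnings.warn(f"{vessel}: single-class labels, skipped",
                          UserWarning, stacklevel=2)
            continue
        model, table = fit_logistic_wald(
            sub[feats].to_numpy(dtype=float), y,
            feature_names=feats, name=f"vessel-involvement:{vessel}",
        )
        model.vessel_class = "vein" if vessel in VEINS else "artery"
        assert set(model.feature_names) == set(feats)
        out[vessel] = (model, table)
    return out
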