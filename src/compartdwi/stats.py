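"""Group comparisons, ROC analysis and cross-validated diagnostic models.

The statistical layer over lesion tables: the Kruskal-Wallis omnibus test
across the three tissue classes, pairwise Mann-Whitney tests at the
multiple-comparison-adjusted level alpha = 0.05/3 = 0.0167, per-parameter
empirical ROC with Youden-threshold operating points, unpenalized logistic
diagnostic models evaluated by stratified five-fold cross-validation, and
the DeLong test for correlated AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .exceptions import InvalidInputError, StratificationError

#: Pairwise significance level (Bonferroni-style for three comparisons).
PAIRWISE_ALPHA = 0.0167
#: Omnibus significance level.
OMNIBUS_ALPHA = 0.05

#: Feature sets of the diagnostic models.
MODEL_FEATURES = {
    "ADC": ["ADC"],
    "IVIM": ["Dt", "Dp", "f"],
    "RSI": ["C1", "C2", "C3", "C1C2", "F1", "F2", "F3", "F1F2"],
    "IVIM+RSI": ["Dt", "Dp", "f", "C1", "C2", "C3", "C1C2", "F1", "F2", "F3", "F1F2"],
}

#: Report-layer display rescaling (diffusivities shown in x10^-3 mm2/s).
DISPLAY_SCALE = {"ADC": 1e3, "Dt": 1e3}

#: Threshold below which the exact Mann-Whitney null is enumerated.
_EXACT_MAX_PAIRS = 400


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H test over >= 3 groups.

    Returns ``(H, p)`` with the chi-square reference on k-1 df.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise InvalidInputError("the omnibus test needs at least 3 groups")
    if any(g.size < 2 for g in groups):
        raise InvalidInputError("every group needs at least 2 observations")
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


@dataclass(frozen=True)
class PairwiseTestResult:
    """Standardized Mann-Whitney outcome at a fixed alpha."""

    u: float
    z: float
    p: float
    alpha: float = PAIRWISE_ALPHA

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def mann_whitney(a, b, alpha: float = PAIRWISE_ALPHA) -> PairwiseTestResult:
    """Two-sided Mann-Whitney U test between two groups.

    Exact enumeration of the null when ``n_a * n_b <= 400`` and the data are
    tie-free; otherwise the tie- and continuity-corrected normal
    approximation.  The reported ``z`` is the standardized U (tie correction
    in the variance, continuity correction toward zero), signed so that a
    negative value means the first group ranks lower.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("both groups need at least 2 observations")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= _EXACT_MAX_PAIRS and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    u = float(res.statistic)
    # standardized statistic with tie and continuity corrections
    n1, n2 = a.size, b.size
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:
        z = 0.0
    else:
        z = float(np.sign(u - mu) * max(abs(u - mu) - 0.5, 0.0) / np.sqrt(var))
    return PairwiseTestResult(u=u, z=z, p=float(res.pvalue), alpha=alpha)


@dataclass(frozen=True)
class ROCSummary:
    """Empirical ROC of a single parameter with a Youden operating point.

    ``direction`` records the sign convention chosen so that auc >= 0.5:
    ``"greater"`` means larger values indicate the positive class and the
    operating rule is ``value > threshold``; ``"less"`` means the rule is
    ``value <= threshold``.
    """

    auc: float
    threshold: float
    sensitivity: float  # percent
    specificity: float  # percent
    direction: str

    @property
    def criterion(self) -> str:
        op = ">" if self.direction == "greater" else "<="
        return f"{op} {self.threshold:g}"


def _midpoint_threshold(values: np.ndarray, cut: float) -> float:
    """Operating cut-point halfway between the decision value and its
    nearest lower observed value (Table-style threshold convention)."""
    lower = values[values < cut]
    if lower.size == 0:
        return float(cut)
    return float((cut + lower.max()) / 2.0)


def roc_single_parameter(values, labels) -> ROCSummary:
    """Empirical ROC of one parameter against binary lesion labels.

    The direction is auto-chosen so that AUC >= 0.5; the operating threshold
    maximizes Youden's J = sensitivity + specificity - 1.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if v.shape != y.shape or v.ndim != 1:
        raise InvalidInputError("values and labels must be paired 1-D vectors")
    if len(np.unique(y)) != 2:
        raise InvalidInputError("both classes must be present")

    direction = "greater"
    scores = v
    fpr, tpr, thr = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    if auc < 0.5:
        direction = "less"
        scores = -v
        fpr, tpr, thr = roc_curve(y, scores)
        auc = float(np.trapezoid(tpr, fpr))

    j = tpr - fpr
    j[0] = -np.inf  # the degenerate all-negative point (threshold = +inf)
    k = int(np.argmax(j))
    cut = float(thr[k])
    threshold = _midpoint_threshold(scores, cut)
    if direction == "less":
        threshold = -threshold
    return ROCSummary(
        auc=auc,
        threshold=threshold,
        sensitivity=float(tpr[k] * 100.0),
        specificity=float((1.0 - fpr[k]) * 100.0),
        direction=direction,
    )


def _auc_mann_whitney(scores: np.ndarray, y: np.ndarray) -> float:
    """Empirical AUC as the normalized Mann-Whitney statistic."""
    x, yneg = scores[y == 1], scores[y == 0]
    psi = (x[:, None] > yneg[None, :]).astype(float)
    psi += 0.5 * (x[:, None] == yneg[None, :])
    return float(psi.mean())


@dataclass
class ModelEvalResult:
    """Cross-validated evaluation of one logistic diagnostic model."""

    model_name: str
    fold_aucs: list[float]
    oof_scores: np.ndarray
    oof_labels: np.ndarray
    seed: int
    features: list[str]
    n_lesions: int
    converged: bool = True

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def pooled_auc(self) -> float:
        return _auc_mann_whitney(self.oof_scores, self.oof_labels)

    def summary(self) -> str:
        folds = ", ".join(f"{a:.3f}" for a in self.fold_aucs)
        return "\n".join([
            f"Diagnostic model: {self.model_name}",
            f"features:   {', '.join(self.features)}",
            f"lesions:    {self.n_lesions}",
            f"fold AUCs:  [{folds}]",
            f"mean AUC:   {self.mean_auc:.3f}",
            f"pooled AUC: {self.pooled_auc:.3f}",
            f"seed:       {self.seed}" + ("" if self.converged else "  (non-converged folds)"),
        ])


class DiagnosticModel:
    """Unpenalized logistic diagnostic model over lesion-table features.

    Built from a lesion table and a class contrast; ``fit()`` runs stratified
    k-fold cross-validation (features standardized on each training split)
    and returns a :class:`ModelEvalResult` with per-fold AUCs and pooled
    out-of-fold scores.
    """

    def __init__(self, table: pd.DataFrame, features: list[str],
                 contrast: tuple[str, str] = ("malignant", "benign"),
                 name: str | None = None):
        missing = [f for f in features if f not in table.columns]
        if missing:
            raise InvalidInputError(f"missing feature columns: {missing}")
        sub = table[table["tissue_class"].isin(contrast)]
        self.x = sub[features].to_numpy(dtype=float)
        self.y = (sub["tissue_class"] == contrast[0]).to_numpy().astype(int)
        self.features = list(features)
        self.contrast = contrast
        self.name = name or "+".join(features)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, model_name: str,
                       contrast: tuple[str, str] = ("malignant", "benign")):
        """Build one of the named models (ADC / IVIM / RSI / IVIM+RSI)."""
        return cls(table, MODEL_FEATURES[model_name], contrast, name=model_name)

    def fit(self, folds: int = 5, seed: int = 0) -> ModelEvalResult:
        counts = np.bincount(self.y, minlength=2)
        if counts.min() < 2 * folds:
            raise StratificationError(
                f"need >= {2 * folds} lesions per class for {folds}-fold "
                f"stratification, got {counts.tolist()}"
            )
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        oof = np.full(self.y.size, np.nan)
        fold_aucs = []
        converged = True
        for train, test in skf.split(self.x, self.y):
            scaler = StandardScaler().fit(self.x[train])
            clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                clf.fit(scaler.transform(self.x[train]), self.y[train])
                if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                    converged = False
            scores = clf.predict_proba(scaler.transform(self.x[test]))[:, 1]
            oof[test] = scores
            fold_aucs.append(_auc_mann_whitney(scores, self.y[test]))
        return ModelEvalResult(
            model_name=self.name, fold_aucs=fold_aucs, oof_scores=oof,
            oof_labels=self.y.copy(), seed=seed, features=self.features,
            n_lesions=self.y.size, converged=converged,
        )


def fit_diagnostic_model(table: pd.DataFrame, features: list[str],
                         contrast: tuple[str, str] = ("malignant", "benign"),
                         folds: int = 5, seed: int = 0) -> ModelEvalResult:
    """Functional wrapper around :class:`DiagnosticModel`."""
    return DiagnosticModel(table, features, contrast).fit(folds=folds, seed=seed)


def delong_compare(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """DeLong test for two correlated empirical AUCs on paired scores.

    Returns ``(auc_a, auc_b, p)`` with the two-sided normal p-value on the
    AUC difference, using the placement-value covariance estimator.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if not (sa.shape == sb.shape == y.shape) or sa.ndim != 1:
        raise InvalidInputError("scores and labels must be paired 1-D vectors")
    if len(np.unique(y)) != 2:
        raise InvalidInputError("both classes must be present")

    pos, neg = y == 1, y == 0
    m, n = int(pos.sum()), int(neg.sum())
    v10 = np.empty((m, 2))
    v01 = np.empty((n, 2))
    aucs = np.empty(2)
    for k, s in enumerate((sa, sb)):
        x, yv = s[pos], s[neg]
        psi = (x[:, None] > yv[None, :]).astype(float)
        psi += 0.5 * (x[:, None] == yv[None, :])
        aucs[k] = psi.mean()
        v10[:, k] = psi.mean(axis=1)  # placement of each positive
        v01[:, k] = psi.mean(axis=0)  # placement of each negative
    s10 = np.cov(v10, rowvar=False)
    s01 = np.cov(v01, rowvar=False)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = aucs[0] - aucs[1]
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), p


# ---------------------------------------------------------------------------
# report builders (CSV/JSON-ready tables over a lesion cohort)
# ---------------------------------------------------------------------------

_CLASS_ORDER = ["malignant", "benign", "normal"]
_CONTRASTS = [("malignant", "benign"), ("malignant", "normal"), ("benign", "normal")]


def _display(parameter: str, value: float) -> float:
    return value * DISPLAY_SCALE.get(parameter, 1.0)


def group_comparison_table(table: pd.DataFrame, parameters: list[str]) -> pd.DataFrame:
    """Per-parameter group descriptives with omnibus and pairwise tests.

    One row per parameter: class means and SDs (diffusivities rescaled to
    the x10^-3 display convention), Kruskal-Wallis H and p, and the
    standardized Mann-Whitney z and p for each class pair at alpha=0.0167.
    """
    present = [c for c in _CLASS_ORDER if (table["tissue_class"] == c).any()]
    rows = []
    for p in parameters:
        groups = {c: table.loc[table["tissue_class"] == c, p].dropna().to_numpy()
                  for c in present}
        row: dict[str, float | str | bool] = {"parameter": p}
        for c in present:
            row[f"{c}_mean"] = _display(p, groups[c].mean())
            row[f"{c}_sd"] = _display(p, groups[c].std(ddof=1))
        if len(present) >= 3:
            h, pk = kruskal_wallis([groups[c] for c in present])
            row["H"], row["p_omnibus"] = h, pk
        for ca, cb in _CONTRASTS:
            if ca in groups and cb in groups:
                res = mann_whitney(groups[ca], groups[cb])
                row[f"z_{ca}_vs_{cb}"] = res.z
                row[f"p_{ca}_vs_{cb}"] = res.p
                row[f"sig_{ca}_vs_{cb}"] = res.significant
        rows.append(row)
    return pd.DataFrame(rows)


def roc_table(table: pd.DataFrame, parameters: list[str],
              contrast: tuple[str, str] = ("malignant", "benign")) -> pd.DataFrame:
    """Per-parameter ROC summary for one class contrast.

    Thresholds are reported on the display scale with the ``> / <=``
    direction convention of the operating rule.
    """
    sub = table[table["tissue_class"].isin(contrast)]
    y = (sub["tissue_class"] == contrast[0]).to_numpy().astype(int)
    rows = []
    for p in parameters:
        roc = roc_single_parameter(sub[p].to_numpy(dtype=float), y)
        rows.append({
            "parameter": p,
            "AUC": roc.auc,
            "threshold": _display(p, roc.threshold),
            "direction": ">" if roc.direction == "greater" else "<=",
            "sensitivity_pct": roc.sensitivity,
            "specificity_pct": roc.specificity,
        })
    return pd.DataFrame(rows)


def model_comparison_report(table: pd.DataFrame,
                            contrast: tuple[str, str] = ("malignant", "benign"),
                            folds: int = 5, seed: int = 0,
                            model_names: list[str] | None = None) -> dict:
    """Cross-validated evaluation of the named diagnostic models.

    Fits each model on the same stratified folds, reports per-fold AUCs and
    mean AUC, and compares every model pair by the DeLong test on the pooled
    out-of-fold scores.
    """
    model_names = model_names or list(MODEL_FEATURES)
    results = {
        name: DiagnosticModel.from_dataframe(table, name, contrast).fit(folds, seed)
        for name in model_names
    }
    report: dict = {
        "contrast": list(contrast),
        "folds": folds,
        "seed": seed,
        "models": {
            name: {
                "features": r.features,
                "fold_aucs": [float(a) for a in r.fold_aucs],
                "mean_auc": r.mean_auc,
                "pooled_auc": r.pooled_auc,
                "converged": r.converged,
            }
            for name, r in results.items()
        },
        "delong": {},
    }
    names = list(results)
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            auc_a, auc_b, p = delong_compare(
                results[na].oof_scores, results[nb].oof_scores,
                results[na].oof_labels,
            )
            report["delong"][f"{na} vs {nb}"] = {
                "auc_a": auc_a, "auc_b": auc_b, "p": p,
            }
    return report
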