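"""Dimensionality reduction, grouped cross-validated models and reports.

The modeling stage reduces each of the five feature families to its first
two principal components (10 columns total across both hands), then fits
penalized linear models under subject-grouped 10-fold cross-validation so
repeated visits of one participant never straddle train and test.
Classification uses L1- or L2-penalized logistic regression; severity
regression uses ridge.  Regularization strength is tuned per outer fold by
an inner grouped 10-fold search over a log-spaced grid.

Interpretability follows the loadings-times-coefficients convention: a
linear model on PC scores is expanded back onto the original standardized
features, so each feature's contribution is the sum over its family's
components of (model coefficient) x (feature loading).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, ParameterError, ValidationError
from .features import family_of_column

FAMILIES = ("TS", "Pk", "Th", "PkTh", "ThTh")
DEFAULT_GRID = np.logspace(-3, 3, 13)

#: BARS grades a single arm 0-4; the parkinsonism arm composite sums three
#: bradykinesia items (text range 0-12, configurable to 24 — demographics
#: tables are consistent with the larger divisor).
BARS_ARM_MAX = 4.0
UPDRS_COMPOSITE_MAX = 12.0


# ---------------------------------------------------------------------------
# Clinical scores
# ---------------------------------------------------------------------------

@dataclass
class ClinicalScores:
    """Raw clinical-scale values for one session."""

    bars_arm_dominant: float = 0.0
    bars_arm_nondominant: float = 0.0
    bars_total: float = 0.0
    updrs_arm_dominant: float = 0.0
    updrs_arm_nondominant: float = 0.0
    updrs_total: float = 0.0

    def validate(self, group: str) -> None:
        if group == "ataxia":
            for name in ("bars_arm_dominant", "bars_arm_nondominant"):
                v = getattr(self, name)
                if not (0 <= v <= BARS_ARM_MAX):
                    raise ValidationError(f"{name}={v} outside [0, {BARS_ARM_MAX}]")
            if not (0 <= self.bars_total <= 30):
                raise ValidationError(f"bars_total={self.bars_total} outside [0, 30]")
        elif group == "parkinsonism":
            for name in ("updrs_arm_dominant", "updrs_arm_nondominant"):
                if getattr(self, name) < 0:
                    raise ValidationError(f"{name} must be non-negative")
            if not (0 <= self.updrs_total <= 108):
                raise ValidationError(f"updrs_total={self.updrs_total} outside [0, 108]")


def common_arm_score(
    scores: ClinicalScores,
    group: str,
    updrs_divisor: float = UPDRS_COMPOSITE_MAX,
) -> tuple[float, float]:
    """Unit-range harmonized arm severity (dominant, nondominant).

    Ataxia: BARS arm score / 4.  Parkinsonism: arm bradykinesia composite /
    ``updrs_divisor``.  Controls are fixed at exactly zero.
    """
    scores.validate(group)
    if group == "control":
        return 0.0, 0.0
    if group == "ataxia":
        return (
            scores.bars_arm_dominant / BARS_ARM_MAX,
            scores.bars_arm_nondominant / BARS_ARM_MAX,
        )
    if group == "parkinsonism":
        return (
            scores.updrs_arm_dominant / updrs_divisor,
            scores.updrs_arm_nondominant / updrs_divisor,
        )
    raise ValidationError(f"unknown group {group!r}")


def add_common_scores(manifest: pd.DataFrame, updrs_divisor: float = UPDRS_COMPOSITE_MAX) -> pd.DataFrame:
    """Append common_arm_dominant / common_arm_nondominant columns."""
    out = manifest.copy()
    d, nd = [], []
    for _, row in manifest.iterrows():
        cs = ClinicalScores(
            bars_arm_dominant=row.get("bars_arm_dominant", 0.0),
            bars_arm_nondominant=row.get("bars_arm_nondominant", 0.0),
            bars_total=row.get("bars_total", 0.0),
            updrs_arm_dominant=row.get("updrs_arm_dominant", 0.0),
            updrs_arm_nondominant=row.get("updrs_arm_nondominant", 0.0),
            updrs_total=row.get("updrs_total", 0.0),
        )
        cd, cnd = common_arm_score(cs, row["group"], updrs_divisor)
        d.append(cd)
        nd.append(cnd)
    out["common_arm_dominant"] = d
    out["common_arm_nondominant"] = nd
    return out


# ---------------------------------------------------------------------------
# Per-family PCA
# ---------------------------------------------------------------------------

@dataclass
class FamilyPCA:
    columns: list[str]
    mean: np.ndarray
    std: np.ndarray
    components: np.ndarray  # (n_components, n_features)
    explained_variance_ratio: np.ndarray


@dataclass
class PCATransform:
    """Per-family standardization + loading matrices (2 PCs per family)."""

    families: dict[str, FamilyPCA] = field(default_factory=dict)
    n_components: int = 2

    @property
    def pc_columns(self) -> list[str]:
        return [
            f"{fam}_pc{c + 1}"
            for fam in self.families
            for c in range(self.n_components)
        ]

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for fam, fp in self.families.items():
            X = df[fp.columns].to_numpy(dtype=float)
            Z = (X - fp.mean) / fp.std
            scores = Z @ fp.components.T
            for c in range(self.n_components):
                cols[f"{fam}_pc{c + 1}"] = scores[:, c]
        return pd.DataFrame(cols, index=df.index)


def fit_family_pca(
    features: pd.DataFrame,
    n_components: int = 2,
) -> tuple[PCATransform, pd.DataFrame]:
    """Standardize and decompose each feature family independently.

    Features are grouped by the family tag of their column name (both
    hands pooled, matching the five-family reduction to 10 columns).
    Constant columns are dropped with a warning before decomposition; the
    deterministic sign convention makes each component's largest-magnitude
    loading positive.
    """
    if len(features) < 3:
        raise InsufficientDataError("PCA needs >= 3 recordings")
    transform = PCATransform(n_components=n_components)
    for fam in FAMILIES:
        cols = [c for c in features.columns if family_of_column(c) == fam]
        if not cols:
            continue
        X = features[cols].to_numpy(dtype=float)
        std = X.std(axis=0)
        # numerically constant columns (e.g. the z-scored amplitude mean,
        # which is ~1e-17 by construction) must go too, or 1/std explodes
        keep = std > 1e-12 * np.maximum(np.abs(X).max(axis=0), 1.0)
        if not keep.all():
            dropped = [c for c, k in zip(cols, keep) if not k]
            warnings.warn(f"family {fam}: dropping constant columns {dropped}", stacklevel=2)
            cols = [c for c, k in zip(cols, keep) if k]
            X, std = X[:, keep], std[keep]
        if len(cols) < 2:
            raise InsufficientDataError(f"family {fam} has < 2 usable features")
        mean = X.mean(axis=0)
        Z = (X - mean) / std
        pca = PCA(n_components=min(n_components, len(cols)), svd_solver="full")
        pca.fit(Z)
        comps = pca.components_
        # Sign convention: the largest-|loading| entry of each PC is positive.
        for c in range(comps.shape[0]):
            j = int(np.argmax(np.abs(comps[c])))
            if comps[c, j] < 0:
                comps[c] = -comps[c]
        n_fit = comps.shape[0]
        evr = pca.explained_variance_ratio_
        if n_fit < n_components:  # degenerate family: pad with zero components
            comps = np.vstack([comps, np.zeros((n_components - n_fit, comps.shape[1]))])
            evr = np.concatenate([evr, np.zeros(n_components - n_fit)])
        transform.families[fam] = FamilyPCA(
            columns=cols, mean=mean, std=std, components=comps,
            explained_variance_ratio=evr,
        )
    reduced = transform.transform(features)
    return transform, reduced


# ---------------------------------------------------------------------------
# Grouped folds
# ---------------------------------------------------------------------------

def grouped_folds(subject_ids: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Subject-level fold assignment with balanced recording counts.

    All recordings of a subject share one fold (repeated visits are
    co-folded).  Subjects are shuffled, then greedily assigned — largest
    recording counts first — to the currently lightest fold; deterministic
    given ``seed``.
    """
    subject_ids = np.asarray(subject_ids)
    subjects, counts = np.unique(subject_ids, return_counts=True)
    if len(subjects) < k:
        raise InsufficientDataError(
            f"{len(subjects)} subjects < k={k}; use a smaller k"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    subjects, counts = subjects[order], counts[order]
    order = np.argsort(-counts, kind="stable")
    subjects, counts = subjects[order], counts[order]
    fold_sizes = np.zeros(k, dtype=int)
    fold_of: dict = {}
    for s, c in zip(subjects, counts):
        f = int(np.argmin(fold_sizes))
        fold_of[s] = f
        fold_sizes[f] += c
    return np.array([fold_of[s] for s in subject_ids])


# ---------------------------------------------------------------------------
# Model reports
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    """Out-of-fold predictions and summary metrics for one fitted contrast."""

    kind: str  # "classification" | "regression"
    contrast: str
    oof: pd.DataFrame  # session_id index; y_true, prediction, fold, subject_id
    metrics: dict
    per_fold_penalty: list[float]
    coefficients: pd.Series  # final model over PC columns
    transform: PCATransform
    positive_label: str | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kind": self.kind,
            "contrast": self.contrast,
            "metrics": self.metrics,
            "per_fold_penalty": self.per_fold_penalty,
            "coefficients": self.coefficients.to_dict(),
            "positive_label": self.positive_label,
            "oof": self.oof.reset_index().to_dict(orient="list"),
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def _sens_spec(y_true: np.ndarray, prob: np.ndarray, threshold: float = 0.5):
    pred = prob >= threshold
    tp = np.sum(pred & (y_true == 1))
    fn = np.sum(~pred & (y_true == 1))
    tn = np.sum(~pred & (y_true == 0))
    fp = np.sum(pred & (y_true == 0))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return float(sens), float(spec)


def _subject_bootstrap_ci(
    stat_fn,
    subject_ids: np.ndarray,
    n_boot: int,
    seed: int,
) -> tuple[float, float]:
    """Percentile 95% CI over subject-level bootstrap resamples."""
    rng = np.random.default_rng(seed)
    subjects = np.unique(subject_ids)
    by_subject = {s: np.nonzero(subject_ids == s)[0] for s in subjects}
    vals = []
    for _ in range(n_boot):
        pick = rng.choice(subjects, size=len(subjects), replace=True)
        idx = np.concatenate([by_subject[s] for s in pick])
        v = stat_fn(idx)
        if v is not None and np.isfinite(v):
            vals.append(v)
    if not vals:
        return np.nan, np.nan
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def _tune_penalty(
    fit_predict,
    score_fn,
    X: pd.DataFrame,
    y: np.ndarray,
    subject_ids: np.ndarray,
    grid: np.ndarray,
    k_inner: int,
    seed: int,
) -> float:
    """Inner grouped-CV grid search; returns the best penalty value."""
    n_subj = len(np.unique(subject_ids))
    k = min(k_inner, n_subj)
    folds = grouped_folds(subject_ids, k=k, seed=seed)
    best_val, best_score = grid[0], -np.inf
    for val in grid:
        preds = np.full(len(y), np.nan)
        ok = True
        for f in range(k):
            tr, te = folds != f, folds == f
            if len(np.unique(y[tr])) < 2 and score_fn is _auc_score:
                ok = False
                break
            preds[te] = fit_predict(X[tr], y[tr], X[te], val)
        if not ok:
            continue
        s = score_fn(y, preds)
        if s > best_score:
            best_score, best_val = s, val
    return float(best_val)


def _auc_score(y, p):
    try:
        return roc_auc_score(y, p)
    except ValueError:
        return -np.inf


def _neg_mse(y, p):
    return -float(np.mean((y - p) ** 2))


def classify(
    features: pd.DataFrame,
    labels: pd.Series,
    subject_ids: pd.Series,
    contrast: str = "",
    penalty: str = "l1",
    k: int = 10,
    seed: int = 0,
    positive_label: str | None = None,
    pca_scope: str = "per-fold",
    grid: np.ndarray = DEFAULT_GRID,
    tune: str = "nested",
    fixed_C: float = 1.0,
    n_bootstrap: int = 1000,
    n_components: int = 2,
) -> ModelReport:
    """Grouped 10-fold cross-validated penalized logistic classification.

    ``features`` is the raw named feature table (one row per session);
    standardization + per-family PCA are fit inside each training fold by
    default (``pca_scope="per-fold"``), or once on all data with
    ``"global"`` to mirror a simpler single-decomposition procedure.
    Regularization is tuned per outer fold by inner grouped CV maximizing
    AUC (``tune="nested"``) or held at ``fixed_C`` (``tune="fixed"``).

    Metrics are computed on pooled out-of-fold probabilities: AUC,
    sensitivity and specificity at probability 0.5, each with a 95%
    subject-level bootstrap CI.
    """
    if penalty not in ("l1", "l2"):
        raise ParameterError(f"penalty must be 'l1' or 'l2', got {penalty!r}")
    y_raw = np.asarray(labels)
    classes = np.unique(y_raw)
    if len(classes) != 2:
        raise ParameterError(f"need exactly 2 classes, got {list(classes)}")
    pos = positive_label if positive_label is not None else classes[0]
    y = (y_raw == pos).astype(int)
    subs = np.asarray(subject_ids)
    for cls in (0, 1):
        if len(np.unique(subs[y == cls])) < k:
            raise InsufficientDataError(
                f"class {cls} has fewer than k={k} subjects; reduce k"
            )

    folds = grouped_folds(subs, k=k, seed=seed)

    def fit_predict(Xtr, ytr, Xte, C):
        model = LogisticRegression(
            penalty=penalty, C=C, solver="liblinear", max_iter=2000, random_state=0
        )
        model.fit(Xtr, ytr)
        return model.predict_proba(Xte)[:, 1]

    global_transform, global_reduced = fit_family_pca(features, n_components)

    prob = np.full(len(y), np.nan)
    per_fold_C: list[float] = []
    for f in range(k):
        tr, te = folds != f, folds == f
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 1:
            raise InsufficientDataError(
                f"fold {f} is single-class; re-seed the fold assignment"
            )
        if pca_scope == "per-fold":
            tf, red_tr = fit_family_pca(features[tr], n_components)
            Xtr, Xte = red_tr.to_numpy(), tf.transform(features[te]).to_numpy()
        else:
            Xtr = global_reduced[tr].to_numpy()
            Xte = global_reduced[te].to_numpy()
        if tune == "nested":
            C = _tune_penalty(
                lambda A, b, B, val: fit_predict(A, b, B, val),
                _auc_score,
                Xtr, y[tr], subs[tr], grid, k_inner=min(10, k), seed=seed + 1000 + f,
            )
        else:
            C = fixed_C
        per_fold_C.append(C)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prob[te] = fit_predict(Xtr, y[tr], Xte, C)

    auc = float(roc_auc_score(y, prob))
    sens, spec = _sens_spec(y, prob)
    seeds = np.random.SeedSequence(seed + 7).generate_state(3)
    auc_ci = _subject_bootstrap_ci(
        lambda idx: roc_auc_score(y[idx], prob[idx]) if len(np.unique(y[idx])) == 2 else None,
        subs, n_bootstrap, int(seeds[0] % 2**31),
    )
    sens_ci = _subject_bootstrap_ci(
        lambda idx: _sens_spec(y[idx], prob[idx])[0], subs, n_bootstrap, int(seeds[1] % 2**31)
    )
    spec_ci = _subject_bootstrap_ci(
        lambda idx: _sens_spec(y[idx], prob[idx])[1], subs, n_bootstrap, int(seeds[2] % 2**31)
    )

    # Final model on all data (global PCA) for the contribution report.
    C_final = float(np.median(per_fold_C))
    final = LogisticRegression(
        penalty=penalty, C=C_final, solver="liblinear", max_iter=2000, random_state=0
    )
    final.fit(global_reduced.to_numpy(), y)
    coeffs = pd.Series(final.coef_[0], index=global_reduced.columns)

    oof = pd.DataFrame(
        {
            "subject_id": subs,
            "y_true": y_raw,
            "prob_positive": prob,
            "fold": folds,
        },
        index=features.index,
    )
    metrics = {
        "auc": auc, "auc_ci": list(auc_ci),
        "sensitivity": sens, "sensitivity_ci": list(sens_ci),
        "specificity": spec, "specificity_ci": list(spec_ci),
        "n": int(len(y)), "n_positive": int(y.sum()),
        "final_C": C_final,
    }
    return ModelReport(
        kind="classification", contrast=contrast, oof=oof, metrics=metrics,
        per_fold_penalty=per_fold_C, coefficients=coeffs,
        transform=global_transform, positive_label=str(pos),
    )


def regress_severity(
    features: pd.DataFrame,
    scores: pd.Series,
    subject_ids: pd.Series,
    target: str = "",
    k: int = 10,
    seed: int = 0,
    pca_scope: str = "per-fold",
    grid: np.ndarray = DEFAULT_GRID,
    tune: str = "nested",
    fixed_alpha: float = 1.0,
    n_bootstrap: int = 1000,
    n_components: int = 2,
) -> ModelReport:
    """Grouped cross-validated ridge regression of a severity score.

    Pooled out-of-fold predictions are summarized by the Pearson
    correlation r with the true scores; r2 is reported as r squared.  The
    report also carries a bootstrap 95% band of the fitted pred-vs-true
    line for plotting.
    """
    y = np.asarray(scores, dtype=float)
    if y.std() == 0:
        raise ParameterError("target scores have zero variance")
    subs = np.asarray(subject_ids)
    folds = grouped_folds(subs, k=k, seed=seed)

    def fit_predict(Xtr, ytr, Xte, alpha):
        model = Ridge(alpha=alpha)
        model.fit(Xtr, ytr)
        return model.predict(Xte)

    global_transform, global_reduced = fit_family_pca(features, n_components)

    pred = np.full(len(y), np.nan)
    per_fold_alpha: list[float] = []
    for f in range(k):
        tr, te = folds != f, folds == f
        if pca_scope == "per-fold":
            tf, red_tr = fit_family_pca(features[tr], n_components)
            Xtr, Xte = red_tr.to_numpy(), tf.transform(features[te]).to_numpy()
        else:
            Xtr = global_reduced[tr].to_numpy()
            Xte = global_reduced[te].to_numpy()
        if tune == "nested":
            alpha = _tune_penalty(
                lambda A, b, B, val: fit_predict(A, b, B, val),
                _neg_mse,
                Xtr, y[tr], subs[tr], grid, k_inner=min(10, k), seed=seed + 2000 + f,
            )
        else:
            alpha = fixed_alpha
        per_fold_alpha.append(alpha)
        pred[te] = fit_predict(Xtr, y[tr], Xte, alpha)

    r, p_r = stats.pearsonr(y, pred)
    r = float(r)
    r_ci = _subject_bootstrap_ci(
        lambda idx: stats.pearsonr(y[idx], pred[idx])[0] if np.std(y[idx]) > 0 else None,
        subs, n_bootstrap, seed + 11,
    )

    # Bootstrap band of the fitted line for a pred-vs-true plot.
    rng = np.random.default_rng(seed + 13)
    xs = np.linspace(y.min(), y.max(), 50)
    lines = []
    for _ in range(min(n_bootstrap, 1000)):
        idx = rng.integers(0, len(y), len(y))
        if np.std(y[idx]) == 0:
            continue
        b1, b0 = np.polyfit(y[idx], pred[idx], 1)
        lines.append(b0 + b1 * xs)
    band_lo, band_hi = (
        np.percentile(lines, [2.5, 97.5], axis=0) if lines else (xs * np.nan, xs * np.nan)
    )

    alpha_final = float(np.median(per_fold_alpha))
    final = Ridge(alpha=alpha_final)
    final.fit(global_reduced.to_numpy(), y)
    coeffs = pd.Series(final.coef_, index=global_reduced.columns)

    oof = pd.DataFrame(
        {"subject_id": subs, "y_true": y, "prediction": pred, "fold": folds},
        index=features.index,
    )
    metrics = {
        "r": r, "r2": r * r, "r_pvalue": float(p_r), "r_ci": list(r_ci),
        "n": int(len(y)), "final_alpha": alpha_final,
        "line_x": xs.tolist(), "line_band_lo": np.asarray(band_lo).tolist(),
        "line_band_hi": np.asarray(band_hi).tolist(),
    }
    return ModelReport(
        kind="regression", contrast=target, oof=oof, metrics=metrics,
        per_fold_penalty=per_fold_alpha, coefficients=coeffs,
        transform=global_transform,
    )


# ---------------------------------------------------------------------------
# Interpretability and diagnostics
# ---------------------------------------------------------------------------

def feature_contributions(
    coefficients: pd.Series,
    transform: PCATransform,
    top_fraction: float = 0.02,
) -> pd.DataFrame:
    """Expand PC-space model weights onto the original standardized features.

    contribution(feature) = sum over its family's PCs of
    (model coefficient for the PC) x (feature loading on the PC).  Signed,
    ranked by magnitude; the top ``top_fraction`` are flagged for plotting.
    Zero-coefficient PCs (as produced by the L1 penalty) contribute zero.
    """
    rows = []
    for fam, fp in transform.families.items():
        w = np.zeros(transform.n_components)
        for c in range(transform.n_components):
            key = f"{fam}_pc{c + 1}"
            if key not in coefficients.index:
                raise ParameterError(f"coefficient {key} missing: transform/model mismatch")
            w[c] = coefficients[key]
        contrib = w @ fp.components  # (n_features,)
        for name, val in zip(fp.columns, contrib):
            rows.append({"feature": name, "family": fam, "contribution": float(val)})
    df = pd.DataFrame(rows)
    df["abs_contribution"] = df["contribution"].abs()
    df = df.sort_values("abs_contribution", ascending=False, ignore_index=True)
    n_top = max(int(np.ceil(top_fraction * len(df))), 1)
    df["top"] = np.arange(len(df)) < n_top
    return df


def diagnostics(
    report: ModelReport,
    ages: pd.Series,
    severities: pd.Series | None = None,
) -> pd.DataFrame:
    """Correlations of the disease-class probability with age and severity.

    Uses the positive-class (disease) probability so the severity relation
    is visible across the pooled cohort.  Constant probabilities make the
    correlation undefined; reported as NaN with a note rather than zero.
    """
    if report.kind != "classification":
        raise ParameterError("diagnostics expects a classification report")
    p_true = report.oof["prob_positive"].to_numpy()
    rows = []
    targets = {"age": np.asarray(ages, dtype=float)}
    if severities is not None:
        targets["severity"] = np.asarray(severities, dtype=float)
    for name, vals in targets.items():
        if len(vals) != len(p_true):
            raise ParameterError(f"{name} length {len(vals)} != {len(p_true)} predictions")
        if np.std(p_true) == 0 or np.std(vals) == 0:
            rows.append({"target": name, "r": np.nan, "p_value": np.nan,
                         "note": "undefined: constant input"})
            continue
        r, p = stats.pearsonr(p_true, vals)
        rows.append({"target": name, "r": float(r), "p_value": float(p), "note": ""})
    return pd.DataFrame(rows)


def group_tscores(features: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-feature Welch two-sample t statistics between the two groups.

    Ranked by |t|; Benjamini-Hochberg adjusted q values are appended
    alongside the raw p values.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ParameterError(f"need exactly 2 groups, got {list(classes)}")
    a = features[y == classes[0]]
    b = features[y == classes[1]]
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    df = pd.DataFrame(
        {"feature": features.columns, "t": t, "p_value": p}
    )
    finite = np.isfinite(df["p_value"])
    q = np.full(len(df), np.nan)
    if finite.any():
        q[finite.to_numpy()] = multipletests(df.loc[finite, "p_value"], method="fdr_bh")[1]
    df["q_value"] = q
    df = df.reindex(df["t"].abs().sort_values(ascending=False).index).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Contrast selection
# ---------------------------------------------------------------------------

def select_contrast(manifest: pd.DataFrame, name: str) -> pd.Series:
    """Boolean session mask for one of the study's group contrasts.

    The manifest must carry ``group``, ``age`` and (for the mild-ataxia
    contrast) ``common_arm_dominant`` columns.
    """
    g = manifest["group"]
    if name == "ataxia_vs_control":
        return g.isin(["ataxia", "control"])
    if name == "ataxia_vs_parkinsonism":
        return g.isin(["ataxia", "parkinsonism"])
    if name == "parkinsonism_vs_control":
        return g.isin(["parkinsonism", "control"])
    if name == "mild_ataxia_vs_control":
        mild = (g == "ataxia") & (manifest["common_arm_dominant"] <= 0.5 / BARS_ARM_MAX)
        return mild | (g == "control")
    if name == "ataxia_vs_control_under45":
        return g.isin(["ataxia", "control"]) & (manifest["age"] < 45)
    if name == "ataxia_vs_parkinsonism_over45":
        return g.isin(["ataxia", "parkinsonism"]) & (manifest["age"] > 45)
    raise ParameterError(f"unknown contrast {name!r}")
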