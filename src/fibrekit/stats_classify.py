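"""Group statistics and LDA classification of the metric database.

The classifier stage follows the standard small-cohort recipe: each of the
29 features is min-max scaled to [-1, 1] and transformed toward a Gaussian
shape, then linear discriminant analysis (LDA) is fitted under stratified
K-fold cross-validation (default K = 6), with all preprocessing statistics
estimated on the training folds only.  Reported are the per-fold
multiclass accuracy, the binary normal-vs-carcinoma accuracy obtained by
regrouping the three carcinoma labels, a 2-component projection for
plotting (with class means and one-standard-deviation ellipses), and
optionally a recursive-feature-elimination curve.

Group comparisons use one-way ANOVA with the conventional significance
stars: p < 0.001 "***", p < 0.01 "**", p < 0.05 "*".
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler, PowerTransformer, QuantileTransformer

NORMAL_LABEL = "normal"


@dataclass
class LabelledDataset:
    """Feature matrix (images x metrics) with per-image diagnosis labels."""

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2D (images x features)")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("label count must match matrix row count")
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match matrix columns")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_column: str = "label") -> "LabelledDataset":
        feats = [c for c in df.columns if c not in (label_column, "field_id")]
        return cls(
            matrix=df[feats].to_numpy(dtype=float),
            labels=df[label_column].to_numpy(),
            feature_names=feats,
        )

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def impute_missing(self) -> "LabelledDataset":
        """Replace NaN sentinels by the per-class feature median (global
        median when a whole class is missing the feature)."""
        x = self.matrix.copy()
        for j in range(x.shape[1]):
            col = x[:, j]
            if not np.isnan(col).any():
                continue
            for lbl in np.unique(self.labels):
                sel = self.labels == lbl
                med = np.nanmedian(col[sel]) if not np.all(np.isnan(col[sel])) else np.nan
                col[sel & np.isnan(col)] = med
            col[np.isnan(col)] = np.nanmedian(col) if not np.all(np.isnan(col)) else 0.0
        return LabelledDataset(x, self.labels.copy(), list(self.feature_names))


@dataclass
class ClassifierReport:
    """Cross-validated LDA results.

    Accuracies are percentages in [0, 100].  ``binary_refit_*`` uses a
    two-class model refitted on regrouped labels, while ``binary_*`` scores
    the multiclass model's predictions after mapping every carcinoma label
    to one group.
    """

    fold_accuracies: list[float]
    accuracy_mean: float
    accuracy_std: float
    binary_fold_accuracies: list[float]
    binary_mean: float
    binary_std: float
    binary_refit_fold_accuracies: list[float]
    binary_refit_mean: float
    binary_refit_std: float
    confusion: pd.DataFrame
    projection: pd.DataFrame
    class_means: pd.DataFrame
    class_ellipses: dict[str, dict] = dc_field(default_factory=dict)
    rfecv_curve: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "fold_accuracies": self.fold_accuracies,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_std": self.accuracy_std,
            "binary_fold_accuracies": self.binary_fold_accuracies,
            "binary_mean": self.binary_mean,
            "binary_std": self.binary_std,
            "binary_refit_fold_accuracies": self.binary_refit_fold_accuracies,
            "binary_refit_mean": self.binary_refit_mean,
            "binary_refit_std": self.binary_refit_std,
            "confusion": self.confusion.to_dict(),
            "class_ellipses": self.class_ellipses,
        }
        if self.rfecv_curve is not None:
            out["rfecv_curve"] = self.rfecv_curve.to_dict(orient="list")
        return out


class _Gaussianizer:
    """Min-max scale to [-1, 1] then transform features toward a Gaussian.

    The default is a rank-based normal-quantile transform; a Yeo-Johnson
    power transform is available as an alternative.  Constant features map
    to all-zeros.  Fit on training data only.
    """

    def __init__(self, method: str = "quantile", seed: int = 0):
        if method not in ("quantile", "power"):
            raise ValueError("method must be 'quantile' or 'power'")
        self.method = method
        self.seed = seed

    def fit(self, x: np.ndarray) -> "_Gaussianizer":
        x = np.asarray(x, dtype=float)
        self.scaler_ = MinMaxScaler(feature_range=(-1.0, 1.0), clip=False).fit(x)
        self.constant_ = self.scaler_.data_range_ == 0
        scaled = self.scaler_.transform(x)
        if self.method == "quantile":
            self.gauss_ = QuantileTransformer(
                output_distribution="normal",
                n_quantiles=min(len(x), 1000),
                subsample=1_000_000,
                random_state=self.seed,
            ).fit(scaled)
        else:
            self.gauss_ = PowerTransformer(method="yeo-johnson").fit(scaled)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        out = self.gauss_.transform(self.scaler_.transform(np.asarray(x, dtype=float)))
        out[:, self.constant_] = 0.0
        return out

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)


def preprocess(data: LabelledDataset, method: str = "quantile", seed: int = 0) -> LabelledDataset:
    """Scale and Gaussianize the whole dataset (no train/test split).

    Inside cross-validation use :class:`_Gaussianizer` per fold instead;
    this convenience variant is for exploratory plots on the full cohort.
    """
    if data.matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    x = _Gaussianizer(method, seed).fit_transform(data.impute_missing().matrix)
    return LabelledDataset(x, data.labels.copy(), list(data.feature_names))


def _make_lda() -> LinearDiscriminantAnalysis:
    # eigen solver + automatic shrinkage: 29 features vs few dozen images
    # per training fold makes the pooled covariance ill-conditioned
    return LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto")


def _binary_labels(labels: np.ndarray, normal_label: str) -> np.ndarray:
    return np.where(labels == normal_label, normal_label, "carcinoma")


def lda_cv(
    data: LabelledDataset,
    k_folds: int = 6,
    seed: int = 0,
    normal_label: str = NORMAL_LABEL,
    gaussianize: str = "quantile",
    run_rfecv: bool = False,
) -> ClassifierReport:
    """Stratified K-fold cross-validated LDA on the metric matrix.

    Per fold, the scaler/Gaussianizer and the LDA are fitted on the
    training part only and scored on the held-out part, so no test-fold
    statistic leaks into preprocessing.  Binary accuracy regroups the
    carcinoma subtypes against the normal class, both by collapsing the
    multiclass model's predictions and by refitting a dedicated two-class
    model on the same folds.  The 2-component projection for plotting comes
    from one fit on the full (preprocessed) cohort.
    """
    data = data.impute_missing()
    classes, counts = np.unique(data.labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    too_small = classes[counts < k_folds]
    if len(too_small):
        raise ValueError(
            f"classes smaller than k_folds={k_folds}: {', '.join(map(str, too_small))}"
        )

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    x, y = data.matrix, data.labels
    y_bin = _binary_labels(y, normal_label)

    fold_acc, bin_acc, bin_refit_acc = [], [], []
    all_true, all_pred = [], []
    for train, test in skf.split(x, y):
        gz = _Gaussianizer(gaussianize, seed).fit(x[train])
        xtr, xte = gz.transform(x[train]), gz.transform(x[test])
        model = _make_lda().fit(xtr, y[train])
        pred = model.predict(xte)
        fold_acc.append(100.0 * float(np.mean(pred == y[test])))
        all_true.extend(y[test])
        all_pred.extend(pred)
        # regrouped predictions of the multiclass model
        pred_bin = _binary_labels(pred, normal_label)
        bin_acc.append(100.0 * float(np.mean(pred_bin == y_bin[test])))
        # dedicated two-class refit on the same fold
        model2 = _make_lda().fit(xtr, y_bin[train])
        bin_refit_acc.append(100.0 * float(np.mean(model2.predict(xte) == y_bin[test])))

    confusion = (
        pd.crosstab(
            pd.Series(all_true, name="true"),
            pd.Series(all_pred, name="predicted"),
            dropna=False,
        )
        .reindex(index=classes, columns=classes)
        .fillna(0)
        .astype(int)
    )

    # full-cohort fit for the 2-component projection (plotting only)
    gz_all = _Gaussianizer(gaussianize, seed).fit(x)
    x_all = gz_all.transform(x)
    n_comp = min(2, len(classes) - 1)
    lda_all = _make_lda()
    lda_all.n_components = n_comp
    proj = lda_all.fit(x_all, y).transform(x_all)[:, :n_comp]
    if n_comp == 1:
        proj = np.column_stack([proj, np.zeros(len(proj))])
    projection = pd.DataFrame(proj, columns=["ld1", "ld2"])
    projection.insert(0, "label", y)

    class_means = projection.groupby("label")[["ld1", "ld2"]].mean()
    ellipses = {}
    for lbl in classes:
        pts = proj[y == lbl]
        cov = np.cov(pts.T) if len(pts) > 1 else np.zeros((2, 2))
        evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
        ellipses[str(lbl)] = {
            "center": pts.mean(axis=0).tolist(),
            "semi_axes": np.sqrt(np.clip(evals, 0, None)).tolist(),
            "angle_deg": float(np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1]))),
        }

    report = ClassifierReport(
        fold_accuracies=fold_acc,
        accuracy_mean=float(np.mean(fold_acc)),
        accuracy_std=float(np.std(fold_acc)),
        binary_fold_accuracies=bin_acc,
        binary_mean=float(np.mean(bin_acc)),
        binary_std=float(np.std(bin_acc)),
        binary_refit_fold_accuracies=bin_refit_acc,
        binary_refit_mean=float(np.mean(bin_refit_acc)),
        binary_refit_std=float(np.std(bin_refit_acc)),
        confusion=confusion,
        projection=projection,
        class_means=class_means,
        class_ellipses=ellipses,
    )
    if run_rfecv:
        report.rfecv_curve = rfecv(data, k_folds=k_folds, seed=seed, gaussianize=gaussianize)
    return report


def rfecv(
    data: LabelledDataset,
    k_folds: int = 6,
    seed: int = 0,
    gaussianize: str = "quantile",
) -> pd.DataFrame:
    """Recursive feature elimination scored by stratified CV.

    At each step the mean CV accuracy of the current feature subset is
    recorded, then the feature with the smallest L2 norm of its LDA
    discriminant coefficients (fitted on the whole preprocessed subset) is
    removed.  Returns a frame with one row per feature count from D down
    to 1.
    """
    data = data.impute_missing()
    if data.matrix.shape[1] < 2:
        raise ValueError("need at least 2 features")
    active = list(range(data.matrix.shape[1]))
    rows = []
    x_full, y = data.matrix, data.labels
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    while active:
        x = x_full[:, active]
        scores = []
        for train, test in skf.split(x, y):
            gz = _Gaussianizer(gaussianize, seed).fit(x[train])
            model = _make_lda().fit(gz.transform(x[train]), y[train])
            scores.append(100.0 * model.score(gz.transform(x[test]), y[test]))
        rows.append(
            {
                "n_features": len(active),
                "cv_score_mean": float(np.mean(scores)),
                "cv_score_std": float(np.std(scores)),
                "features": [data.feature_names[i] for i in active],
            }
        )
        if len(active) == 1:
            break
        gz = _Gaussianizer(gaussianize, seed).fit(x)
        model = _make_lda().fit(gz.transform(x), y)
        weights = np.linalg.norm(np.atleast_2d(model.coef_), axis=0)
        active.pop(int(np.argmin(weights)))
    return pd.DataFrame(rows)


def anova_stars(
    data: LabelledDataset, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-metric one-way ANOVA between two diagnosis groups.

    Returns a frame with columns F, p and stars ("***" p<0.001, "**"
    p<0.01, "*" p<0.05, "" otherwise).  Two identical constant groups give
    p = 1 rather than NaN.
    """
    sel_a = data.labels == group_a
    sel_b = data.labels == group_b
    if sel_a.sum() < 2 or sel_b.sum() < 2:
        raise ValueError("both groups need at least 2 members")
    rows = []
    for j, name in enumerate(data.feature_names):
        a = data.matrix[sel_a, j]
        b = data.matrix[sel_b, j]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) < 2 or len(b) < 2:
            f_val, p = float("nan"), float("nan")
        elif np.var(a) == 0 and np.var(b) == 0:
            f_val, p = (0.0, 1.0) if np.mean(a) == np.mean(b) else (float("inf"), 0.0)
        else:
            f_val, p = stats.f_oneway(a, b)
        rows.append({"metric": name, "F": float(f_val), "p": float(p), "stars": significance_stars(p)})
    return pd.DataFrame(rows).set_index("metric")


def significance_stars(p: float) -> str:
    """Conventional significance stars for a p value."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
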