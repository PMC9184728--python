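"""Feature-matrix construction and the ML stack around DIC prediction.

Sites x features matrices combine binary co-localization columns (1 iff a
dataset's intervals overlap the site by >= 1 bp) with z-scored continuous
columns.  On top of that matrix sit: unsupervised k-means clustering
(k = 10 in the full analysis), SMOTE over-sampling of the rare DIC class,
L2/L1-penalized logistic classification evaluated on chromosome-held-out
test sites, signed-coefficient feature importance, elastic-net feature
selection against the M-value response with univariate follow-up fits, and
cross-cell-type prediction on a shared feature subset scored by a
hypergeometric overlap test.

The logistic model is P(Y_i = 1 | X_i) = 1 / (1 + exp(-(b0 + sum_j b_j
X_ij))); the elastic-net loss is RSS/(2n) + lambda * ((1 - alpha)/2 *
sum b^2 + alpha * sum |b|), lambda chosen by cross-validation at a fixed
L1/L2 mix alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.linear_model import ElasticNet, ElasticNetCV, LinearRegression, LogisticRegression
from sklearn.metrics import average_precision_score, confusion_matrix, roc_auc_score
from sklearn.model_selection import KFold

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

def build_feature_matrix(sites: pd.DataFrame,
                         binary_datasets: dict[str, pd.DataFrame],
                         continuous_tracks: dict[str, np.ndarray],
                         ) -> pd.DataFrame:
    """Sites x features matrix: binary overlap columns + z-scored continuous.

    ``binary_datasets`` maps feature name to an interval table; the column
    is 1 iff the site overlaps any interval by >= 1 bp.  Each continuous
    track supplies one value per site and is z-scored; a track with zero
    variance is dropped with a warning.  The result keeps the site name as
    index and carries a ``chrom`` column for held-out splits.
    """
    idx = sites["name"] if "name" in sites.columns else sites.index.astype(str)
    out = pd.DataFrame(index=pd.Index(idx, name="name"))
    out["chrom"] = sites["chrom"].to_numpy()

    starts = sites["start"].to_numpy()
    ends = sites["end"].to_numpy()
    chroms = sites["chrom"].to_numpy()
    for feat, table in binary_datasets.items():
        col = np.zeros(len(sites), dtype=float)
        by_chrom = {c: (df["start"].to_numpy(), df["end"].to_numpy())
                    for c, df in table.groupby("chrom")}
        for k in range(len(sites)):
            hit = by_chrom.get(chroms[k])
            if hit is None:
                continue
            col[k] = float(((hit[0] < ends[k]) & (hit[1] > starts[k])).any())
        out[feat] = col

    for feat, vals in continuous_tracks.items():
        v = np.asarray(vals, float)
        if len(v) != len(sites):
            raise ValueError(f"continuous track {feat!r} length mismatch")
        sd = v.std(ddof=0)
        if sd == 0:
            warnings.warn(f"continuous feature {feat!r} has zero variance; dropped")
            continue
        out[feat] = (v - v.mean()) / sd
    if out.drop(columns="chrom").isna().any().any():
        raise ValueError("feature matrix contains missing values")
    return out


def feature_columns(X: pd.DataFrame) -> list[str]:
    return [c for c in X.columns if c != "chrom"]


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def kmeans_cluster(X: pd.DataFrame, k: int = 10, seed: int = 0,
                   restarts: int = 10) -> tuple[np.ndarray, pd.DataFrame]:
    """k-means with greedy (k-means++) seeding and fixed restarts.

    Returns the assignment and the per-cluster feature-mean table (the
    substrate of the cluster heatmap).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cols = feature_columns(X)
    mat = X[cols].to_numpy(float)
    if k > len(mat):
        raise ValueError("k cannot exceed the number of rows")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    assign = km.fit_predict(mat)
    means = pd.DataFrame(km.cluster_centers_, columns=cols)
    means.index.name = "cluster"
    return assign, means


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    test_chroms: list[str]
    folds: int
    seed: int
    test_index: np.ndarray               # positional indices
    fold_assignment: np.ndarray          # -1 for test rows, else fold id


def make_split(X: pd.DataFrame, test_chroms: list[str], folds: int = 5,
               seed: int = 0) -> SplitSpec:
    """Chromosome-held-out test set + k-fold CV assignment on the remainder."""
    chrom = X["chrom"].to_numpy()
    test_mask = np.isin(chrom, test_chroms)
    if not test_mask.any():
        raise ValueError("test chromosome set selects no rows")
    train_idx = np.nonzero(~test_mask)[0]
    if len(train_idx) == 0:
        raise ValueError("no rows left for training")
    if len(train_idx) < folds:
        raise ValueError("fewer training rows than folds")
    fold = np.full(len(X), -1, dtype=int)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for f, (_, val) in enumerate(kf.split(train_idx)):
        fold[train_idx[val]] = f
    return SplitSpec(test_chroms=list(test_chroms), folds=folds, seed=seed,
                     test_index=np.nonzero(test_mask)[0],
                     fold_assignment=fold)


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote_oversample(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5,
                     seed: int = 0, binary_columns: list[int] | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority over-sampling to exactly balanced classes.

    Each synthetic row is x_i + u * (x_nn - x_i) with u ~ Uniform(0, 1) and
    x_nn one of the k nearest minority neighbors of x_i (Euclidean).
    Binary columns of synthetic rows are rounded back to {0, 1}.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE needs exactly two classes")
    minority = classes[np.argmin(counts)]
    maj_n, min_n = counts.max(), counts.min()
    if min_n < 2:
        raise ValueError("minority class needs at least 2 members")
    k = min(k_neighbors, min_n - 1)
    if k < 1:
        raise ValueError("k_neighbors must leave at least one neighbor")
    need = maj_n - min_n
    if need == 0:
        return X.copy(), y.copy()

    rng = np.random.default_rng(seed)
    Xm = X[y == minority]
    # pairwise distances within the minority class
    d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1)[:, :k]

    base = rng.integers(0, min_n, size=need)
    pick = nn[base, rng.integers(0, k, size=need)]
    u = rng.uniform(0.0, 1.0, size=need)[:, None]
    synth = Xm[base] + u * (Xm[pick] - Xm[base])
    if binary_columns:
        synth[:, binary_columns] = np.round(synth[:, binary_columns])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(need, minority)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# Logistic model
# ---------------------------------------------------------------------------

@dataclass
class LogisticModel:
    intercept: float
    coefficients: np.ndarray
    feature_names: list[str]
    penalty: str = "l2"
    C: float = 1.0

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.intercept + np.asarray(X, float) @ self.coefficients
        return 1.0 / (1.0 + np.exp(-z))


def train_logistic(X: np.ndarray, y: np.ndarray,
                   feature_names: list[str] | None = None,
                   penalty: str = "l2", C: float = 1.0,
                   seed: int = 0) -> LogisticModel:
    """Penalized maximum-likelihood logistic regression."""
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if penalty == "l1":
        clf = LogisticRegression(C=C, l1_ratio=1, solver="liblinear",
                                 max_iter=2000, random_state=seed)
    else:
        clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)
    clf.fit(np.asarray(X, float), y)
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    return LogisticModel(intercept=float(clf.intercept_[0]),
                         coefficients=clf.coef_.ravel().copy(),
                         feature_names=list(names), penalty=penalty, C=C)


def evaluate_classifier(model: LogisticModel, X_test: np.ndarray,
                        y_test: np.ndarray) -> dict:
    """AUROC (rank statistic, ties averaged), average precision, confusion."""
    if len(y_test) == 0:
        raise ValueError("empty test set")
    prob = model.predict_proba(X_test)
    y = np.asarray(y_test, int)
    out: dict = {"n": len(y)}
    if len(np.unique(y)) < 2:
        out["auroc"] = None
        out["average_precision"] = None
    else:
        out["auroc"] = float(roc_auc_score(y, prob))
        out["average_precision"] = float(average_precision_score(y, prob))
    pred = (prob >= 0.5).astype(int)
    out["confusion"] = confusion_matrix(y, pred, labels=[0, 1])
    return out


def feature_importance(model: LogisticModel) -> pd.DataFrame:
    """Signed coefficients ranked by magnitude (features pre-standardized)."""
    imp = pd.DataFrame({"feature": model.feature_names,
                        "importance": model.coefficients})
    dup = imp["feature"].duplicated()
    if dup.any():
        warnings.warn("duplicated feature names: collinear weight is split")
    return imp.reindex(
        imp["importance"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Elastic net
# ---------------------------------------------------------------------------

@dataclass
class ElasticNetModel:
    lam: float                         # penalty strength (lambda)
    alpha: float                       # L1/L2 mix
    intercept: float
    coefficients: np.ndarray
    feature_names: list[str]
    survivors: list[str] = field(default_factory=list)


def elastic_net_select(X: np.ndarray, y: np.ndarray,
                       feature_names: list[str] | None = None,
                       alpha: float = 0.5, lam_grid=None, folds: int = 5,
                       rule: str = "1se", seed: int = 0) -> ElasticNetModel:
    """Minimize the elastic-net loss; lambda chosen by cross-validation.

    ``rule="1se"`` (default) picks the largest lambda whose CV error lies
    within one standard error of the minimum — the conventional choice when
    the fit is used for feature selection, as it prunes noise survivors
    that the minimum-error lambda retains.  ``rule="min"`` takes the
    minimum-CV-error lambda.  ``lam_grid`` may be a scalar (fixed lambda;
    0 falls back to ordinary least squares) or an explicit grid.  Survivors
    are the features with nonzero coefficients after a tight-tolerance
    refit at the selected lambda.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if not np.isfinite(y).all():
        raise ValueError("response must be finite")
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]

    if lam_grid is not None and np.isscalar(lam_grid):
        lam = float(lam_grid)
    else:
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
        encv = ElasticNetCV(l1_ratio=alpha,
                            alphas=lam_grid if lam_grid is not None else 100,
                            cv=cv, max_iter=50_000)
        encv.fit(X, y)
        mse = encv.mse_path_.mean(axis=1)
        if rule == "min":
            lam = float(encv.alpha_)
        elif rule == "1se":
            se = encv.mse_path_.std(axis=1, ddof=1) / np.sqrt(folds)
            i_min = int(np.argmin(mse))
            within = np.nonzero(mse <= mse[i_min] + se[i_min])[0]
            lam = float(encv.alphas_[within.min()])  # alphas descend
        else:
            raise ValueError(f"unknown rule {rule!r}")

    if lam == 0.0:
        ols = LinearRegression().fit(X, y)
        coef, intercept = ols.coef_.copy(), float(ols.intercept_)
    else:
        en = ElasticNet(alpha=lam, l1_ratio=alpha, max_iter=200_000, tol=1e-10)
        en.fit(X, y)
        coef, intercept = en.coef_.copy(), float(en.intercept_)

    survivors = [names[j] for j in np.nonzero(coef)[0]]
    if not survivors:
        warnings.warn("all coefficients shrunk to zero: empty survivor list")
    return ElasticNetModel(lam=lam, alpha=alpha, intercept=intercept,
                           coefficients=coef, feature_names=list(names),
                           survivors=survivors)


def subgradient_residual(model: ElasticNetModel, X: np.ndarray,
                         y: np.ndarray) -> float:
    """Max violation of the elastic-net subgradient optimality conditions.

    At the optimum, for each feature j: g_j = lam*(1-alpha)*b_j +
    lam*alpha*sign(b_j) when b_j != 0, and |g_j| <= lam*alpha when b_j = 0,
    where g_j = x_j'(y - yhat)/n.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    resid = y - (model.intercept + X @ model.coefficients)
    g = X.T @ resid / n
    lam, a = model.lam, model.alpha
    b = model.coefficients
    viol = np.where(
        b != 0,
        np.abs(g - lam * (1 - a) * b - lam * a * np.sign(b)),
        np.maximum(np.abs(g) - lam * a, 0.0))
    return float(np.max(viol))


def univariate_coefficients(X: np.ndarray, y: np.ndarray,
                            model: ElasticNetModel) -> pd.DataFrame:
    """OLS fit y = a + b x for each surviving feature."""
    X = np.asarray(X, float)
    rows = []
    for name in model.survivors:
        j = model.feature_names.index(name)
        res = stats.linregress(X[:, j], y)
        rows.append({"feature": name, "intercept": float(res.intercept),
                     "slope": float(res.slope), "p": float(res.pvalue)})
    return pd.DataFrame(rows, columns=["feature", "intercept", "slope", "p"])


# ---------------------------------------------------------------------------
# Supervised DIC prediction (end-to-end convenience)
# ---------------------------------------------------------------------------

def train_dic_classifier(X: pd.DataFrame, y: np.ndarray, split: SplitSpec,
                         smote_k: int = 5, C: float = 1.0, seed: int = 0,
                         ) -> tuple[LogisticModel, dict]:
    """Train on non-test chromosomes with SMOTE, evaluate on held-out test.

    SMOTE is applied to the training rows only; no test-chromosome row
    influences training.
    """
    cols = feature_columns(X)
    mat = X[cols].to_numpy(float)
    y = np.asarray(y, int)
    test_idx = split.test_index
    train_mask = split.fold_assignment >= 0
    binary_cols = [j for j, c in enumerate(cols)
                   if set(np.unique(mat[:, j])) <= {0.0, 1.0}]
    Xb, yb = smote_oversample(mat[train_mask], y[train_mask],
                              k_neighbors=smote_k, seed=seed,
                              binary_columns=binary_cols)
    model = train_logistic(Xb, yb, feature_names=cols, C=C, seed=seed)
    metrics = evaluate_classifier(model, mat[test_idx], y[test_idx])
    return model, metrics


def predict_cross(model: LogisticModel, X_other: pd.DataFrame,
                  experimental_calls: np.ndarray,
                  threshold: float = 0.5) -> dict:
    """Apply a model to another cell type restricted to shared features.

    ``X_other`` must carry exactly the model's feature columns (plus
    chrom); any mismatch is a hard error.  Predicted positives are
    intersected with experimental calls and scored with the upper-tail
    hypergeometric test.
    """
    cols = feature_columns(X_other)
    if list(cols) != list(model.feature_names):
        raise ValueError("shared feature names must match the model exactly")
    prob = model.predict_proba(X_other[cols].to_numpy(float))
    pred = prob >= threshold
    exp = np.asarray(experimental_calls, bool)
    k = int((pred & exp).sum())
    from .loopstats import hypergeom_overlap
    res = hypergeom_overlap(k, int(exp.sum()), int(pred.sum()), len(exp))
    return {"predicted": pred, "probability": prob, "overlap": k,
            "n_predicted": int(pred.sum()), "n_experimental": int(exp.sum()),
            "p": res.p}
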