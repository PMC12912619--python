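"""Stage classification from SUVR + network features.

Workflow (train data only at every selection step):

1. assemble a feature matrix — regional SUVRs (``suvr.<roi>``), global
   network AUC metrics (``global.<metric>``) and nodal AUC metrics
   (``nodal.<metric>.<roi>``);
2. stratified 70/30 train/test split;
3. z-standardization with parameters fit on the train split;
4. univariate filtering (normality-gated two-group test at alpha);
5. LASSO (L1 logistic) selection, lambda by 5-fold CV;
6. one of six classifier families, hyperparameters tuned by 5-fold CV
   AUC on the train split; accuracy / sensitivity / specificity / AUC on
   train and test with stratified-bootstrap 95% CIs.

The later disease stage is the positive class throughout, so sensitivity
is the detection rate of the more affected group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import stats as gstats
from .metrics import MetricTable
from .suvr import SuvrMatrix

__all__ = [
    "FeatureMatrix", "ModelReport", "assemble_features", "stratified_split",
    "standardize", "univariate_filter", "lasso_select", "train_evaluate",
    "run_task_suite", "CLASSIFIER_FAMILIES", "DEFAULT_TASKS",
]

#: Stage order; the later stage of a task is the positive class.
STAGE_ORDER = ("CN", "EMCI", "LMCI", "AD")
DEFAULT_TASKS = (("CN", "AD"), ("CN", "EMCI"), ("EMCI", "LMCI"),
                 ("LMCI", "AD"))


@dataclass
class FeatureMatrix:
    """Namespaced feature table with binary labels and a split assignment."""

    values: pd.DataFrame               # subjects x features
    labels: pd.Series                  # 0/1, 1 = later stage
    task: tuple[str, str]
    split: pd.Series | None = None     # 'train' / 'test'

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            raise ValueError("feature and label subjects differ")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValueError(f"missing values in features: {bad}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate feature names")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def rows(self, which: str) -> pd.Index:
        if self.split is None:
            raise ValueError("no split assigned")
        return self.split.index[self.split == which]

    def xy(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        ids = self.rows(which)
        return (self.values.loc[ids].to_numpy(dtype=float),
                self.labels.loc[ids].to_numpy(dtype=int))

    def select(self, names: list[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.values[list(names)].copy(), self.labels,
                             self.task, self.split)


@dataclass
class ModelReport:
    task: tuple[str, str]
    family: str
    hyperparameters: dict
    selected_features: list[str]
    seed: int
    metrics: dict = field(default_factory=dict)   # split -> metric -> (pt, lo, hi)
    roc_points: dict = field(default_factory=dict)
    cv_auc: float = float("nan")

    def as_row(self, split: str) -> dict:
        row = {"task": f"{self.task[0]} vs {self.task[1]}",
               "classifier": self.family, "split": split,
               "cv_auc": self.cv_auc}
        for name, (pt, lo, hi) in self.metrics[split].items():
            row[name] = pt
            row[f"{name}_ci_low"] = lo
            row[f"{name}_ci_high"] = hi
        return row


def assemble_features(suvr: SuvrMatrix | pd.DataFrame,
                      global_auc: pd.DataFrame | None,
                      nodal_auc: pd.DataFrame | None,
                      labels: pd.Series,
                      task: tuple[str, str]) -> FeatureMatrix:
    """Concatenate SUVR + network AUC features for one binary task.

    Subjects are restricted to the two task groups; the later disease
    stage (by CN < EMCI < LMCI < AD) is labelled 1.
    """
    suvr_df = suvr.values if isinstance(suvr, SuvrMatrix) else suvr
    parts = [suvr_df.rename(columns=lambda c: f"suvr.{c}")]
    if global_auc is not None:
        parts.append(global_auc.rename(columns=lambda c: f"global.{c}"))
    if nodal_auc is not None:
        parts.append(nodal_auc.rename(columns=lambda c: f"nodal.{c}"))
    base = parts[0]
    for extra in parts[1:]:
        mismatch = set(base.index) ^ set(extra.index)
        if mismatch:
            raise ValueError(f"subject sets differ between feature blocks: "
                             f"{sorted(mismatch)[:5]}...")
        base = base.join(extra)
    labels = labels.reindex(base.index)
    a, b = task
    order = {g: k for k, g in enumerate(STAGE_ORDER)}
    if order[b] < order[a]:
        a, b = b, a
    keep = labels.isin([a, b])
    values = base.loc[keep]
    y = (labels.loc[keep] == b).astype(int)
    # drop features that are constant over the task cohort (no information,
    # and they break standardization)
    nunique = values.nunique()
    values = values.loc[:, nunique > 1]
    return FeatureMatrix(values, y, task=(a, b))


def stratified_split(fm: FeatureMatrix, train_fraction: float = 0.7,
                     seed: int = 0) -> FeatureMatrix:
    """Assign a stratified train/test split (disjoint, exhaustive)."""
    counts = fm.labels.value_counts()
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 subjects to stratify")
    train_ids, test_ids = train_test_split(
        fm.values.index, train_size=train_fraction, random_state=seed,
        stratify=fm.labels)
    split = pd.Series("test", index=fm.values.index)
    split.loc[train_ids] = "train"
    return FeatureMatrix(fm.values, fm.labels, fm.task, split)


def standardize(fm: FeatureMatrix) -> FeatureMatrix:
    """Z-standardize using mean/SD fit on the train split only."""
    train_ids = fm.rows("train")
    mu = fm.values.loc[train_ids].mean()
    sd = fm.values.loc[train_ids].std(ddof=0).replace(0.0, 1.0)
    values = (fm.values - mu) / sd
    return FeatureMatrix(values, fm.labels, fm.task, fm.split)


def univariate_filter(fm: FeatureMatrix, alpha: float = 0.05,
                      ) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Keep features whose train-split two-group test has p < alpha.

    Test selection per feature follows the normality gate (t vs
    Mann-Whitney).  Returns the reduced matrix plus a ledger of decisions.
    """
    train_ids = fm.rows("train")
    y = fm.labels.loc[train_ids]
    if y.value_counts().min() < 3:
        raise ValueError("need >= 3 train subjects per class")
    a_ids = y.index[y == 0]
    b_ids = y.index[y == 1]
    keep, records = [], []
    for col in fm.values.columns:
        res = gstats.compare_groups(
            fm.values.loc[a_ids, col].to_numpy(),
            fm.values.loc[b_ids, col].to_numpy(),
            feature_name=col, corrected_alpha=alpha)
        if res.significant:
            keep.append(col)
        records.append({"feature": col, "test": res.test_used,
                        "p_value": res.p_value, "kept": res.significant})
    if not keep:
        raise ValueError(f"univariate filter at alpha={alpha} removed every "
                         "feature; raise alpha")
    return fm.select(keep), pd.DataFrame(records)


def lasso_select(fm: FeatureMatrix, n_folds: int = 5, seed: int = 0,
                 n_lambdas: int = 25) -> tuple[list[str], float]:
    """L1-penalized logistic selection; lambda by minimum mean CV loss.

    Returns the features with nonzero coefficients at the chosen lambda
    and the lambda itself (= 1/C on sklearn's scale).
    """
    x, y = fm.xy("train")
    if min(np.bincount(y)) < n_folds:
        raise ValueError("too few subjects per class for the CV folds")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        Cs=np.logspace(-3, 2, n_lambdas), cv=cv, penalty="l1",
        solver="liblinear", scoring="neg_log_loss", max_iter=2000,
        random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(x, y)
    coefs = model.coef_.ravel()
    selected = [n for n, c in zip(fm.feature_names, coefs) if c != 0.0]
    lam = float(1.0 / model.C_[0])
    if not selected:
        warnings.warn("LASSO shrank every coefficient to zero",
                      RuntimeWarning)
    return selected, lam


def _default_families(seed: int) -> dict[str, tuple[object, dict]]:
    return {
        "SVM": (SVC(probability=True, random_state=seed),
                {"C": [0.1, 1, 10], "kernel": ["rbf", "linear"]}),
        "RF": (RandomForestClassifier(random_state=seed),
               {"n_estimators": [100, 500]}),
        "LR": (LogisticRegression(max_iter=2000, random_state=seed),
               {"C": [0.1, 1, 10]}),
        "MLP": (MLPClassifier(max_iter=3000, random_state=seed),
                {"hidden_layer_sizes": [(16,), (64,)]}),
        "XGBoost": (XGBClassifier(eval_metric="logloss", random_state=seed,
                                  n_estimators=200, learning_rate=0.1),
                    {"max_depth": [2, 3, 4]}),
        "kNN": (KNeighborsClassifier(),
                {"n_neighbors": [3, 5, 7, 11]}),
    }


CLASSIFIER_FAMILIES = tuple(_default_families(0))


def _scores(model, x: np.ndarray) -> np.ndarray:
    return model.predict_proba(x)[:, 1]


def _binary_metrics(y: np.ndarray, score: np.ndarray,
                    threshold: float = 0.5) -> dict[str, float]:
    pred = (score >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return {
        "accuracy": (tp + tn) / len(y),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "auc": float(roc_auc_score(y, score)),
    }


def _bootstrap_ci(y: np.ndarray, score: np.ndarray, n_boot: int, seed: int,
                  ) -> dict[str, tuple[float, float, float]]:
    """Stratified bootstrap percentile CIs for all four metrics."""
    rng = np.random.default_rng(seed)
    point = _binary_metrics(y, score)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    samples: dict[str, list[float]] = {k: [] for k in point}
    for _ in range(n_boot):
        take = np.concatenate([rng.choice(idx0, size=len(idx0)),
                               rng.choice(idx1, size=len(idx1))])
        m = _binary_metrics(y[take], score[take])
        for k, v in m.items():
            samples[k].append(v)
    out = {}
    for k, v in point.items():
        lo, hi = np.nanpercentile(samples[k], [2.5, 97.5])
        out[k] = (v, float(lo), float(hi))
    return out


def train_evaluate(fm: FeatureMatrix, family: str = "LR",
                   tuning_grid: dict | None = None, seed: int = 0,
                   n_folds: int = 5, n_boot: int = 2000) -> ModelReport:
    """Tune one classifier family by CV AUC on the train split and report
    train/test metrics with stratified-bootstrap 95% CIs."""
    families = _default_families(seed)
    if family not in families:
        raise ValueError(f"unknown family {family!r}; "
                         f"allowed: {sorted(families)}")
    base, grid = families[family]
    grid = tuning_grid if tuning_grid is not None else grid
    x_tr, y_tr = fm.xy("train")
    x_te, y_te = fm.xy("test")
    if len(np.unique(y_te)) < 2 or len(np.unique(y_tr)) < 2:
        raise ValueError("both classes required in each evaluation split")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(base, grid, scoring="roc_auc", cv=cv, refit=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(x_tr, y_tr)
    model = search.best_estimator_
    report = ModelReport(task=fm.task, family=family,
                         hyperparameters=dict(search.best_params_),
                         selected_features=fm.feature_names, seed=seed,
                         cv_auc=float(search.best_score_))
    for split, (x, y) in (("train", (x_tr, y_tr)), ("test", (x_te, y_te))):
        score = _scores(model, x)
        report.metrics[split] = _bootstrap_ci(y, score, n_boot, seed)
        fpr, tpr, _ = roc_curve(y, score)
        report.roc_points[split] = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    report.model_ = model
    return report


def run_task_suite(suvr: SuvrMatrix | pd.DataFrame,
                   global_auc: pd.DataFrame | None,
                   nodal_auc: pd.DataFrame | None,
                   labels: pd.Series,
                   tasks: tuple = DEFAULT_TASKS,
                   families: tuple = CLASSIFIER_FAMILIES,
                   filter_alpha: float = 0.05,
                   train_fraction: float = 0.7,
                   seed: int = 0, n_boot: int = 2000,
                   skip_filter: bool = False,
                   ) -> dict[tuple[str, str], ModelReport]:
    """End-to-end classification for each binary task.

    For each task the full chain runs (split, standardize, filter, LASSO,
    family tuning) and the family with the best CV AUC is reported.
    Tasks whose groups are missing from the cohort are skipped with a
    warning.
    """
    reports: dict[tuple[str, str], ModelReport] = {}
    present = set(labels.unique())
    for task in tasks:
        if not set(task) <= present:
            warnings.warn(f"task {task}: group(s) missing; skipped",
                          RuntimeWarning)
            continue
        fm = assemble_features(suvr, global_auc, nodal_auc, labels, task)
        fm = stratified_split(fm, train_fraction=train_fraction, seed=seed)
        fm = standardize(fm)
        if not skip_filter:
            try:
                fm, _ = univariate_filter(fm, alpha=filter_alpha)
            except ValueError:
                warnings.warn(f"task {task}: univariate filter removed all "
                              "features; continuing unfiltered",
                              RuntimeWarning)
        selected, _ = lasso_select(fm, seed=seed)
        if selected:
            fm = fm.select(selected)
        best: ModelReport | None = None
        for family in families:
            rep = train_evaluate(fm, family=family, seed=seed,
                                 n_boot=n_boot)
            if best is None or rep.cv_auc > best.cv_auc:
                best = rep
        best.feature_matrix_ = fm
        reports[task] = best
    return reports
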