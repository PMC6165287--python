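"""Feature screening and impaired-gait classification.

The 12 per-sequence biomechanical features (step lengths and their symmetry,
foot-flat ratios, speed, normalized step count, torso orientation, COG shift,
and the amount-of-movement triple) are screened one at a time with Welch's
unequal-variance t-test against the normal-gait group, and fed jointly to a
quadratic-kernel support vector machine that labels a sequence as normal
(NM), full-body impaired (FB), right-leg impaired (RL) or left-leg impaired
(LL). Evaluation uses subject-exclusive fivefold cross-validation: folds
partition the subjects, never just the sequences, so no individual appears
in both a training and a test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as sk_confusion_matrix
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DegenerateInputError, GaitSilError

CLASS_ORDER = ("FB", "RL", "LL", "NM")

FEATURE_COLUMNS = (
    "SL_left",
    "SL_right",
    "SL_symm",
    "FFR_left",
    "FFR_right",
    "S",
    "C",
    "TO",
    "COG_shift",
    "AOM_left",
    "AOM_right",
    "AOM_symm",
)


@dataclass(frozen=True)
class TTestResult:
    """Welch two-sample t-test outcome."""

    t: float
    df: float
    p: float
    reject: bool
    alpha: float = 0.05


@dataclass(eq=False)
class CVResult:
    """Subject-exclusive k-fold cross-validation outcome."""

    fold_subjects: list[list]
    fold_accuracies: list[float]
    mean_accuracy: float
    confusion: pd.DataFrame  # true x predicted counts, CLASS_ORDER


def welch_ttest(
    sample_a,
    sample_b,
    alpha: float = 0.05,
) -> TTestResult:
    """Two-sample t-test with unequal variances (Welch).

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b), with
    Welch-Satterthwaite degrees of freedom and a two-sided p-value from the
    t distribution. Two identical zero-variance samples give p = 1 by
    convention; distinct zero-variance samples give p = 0.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each sample needs n >= 2")
    va = a.var(ddof=1) / a.size
    vb = b.var(ddof=1) / b.size
    denom = va + vb
    diff = a.mean() - b.mean()
    if denom == 0:
        df = float(a.size + b.size - 2)
        if diff == 0:
            return TTestResult(t=0.0, df=df, p=1.0, reject=False, alpha=alpha)
        t_inf = float("inf") if diff > 0 else float("-inf")
        return TTestResult(t=t_inf, df=df, p=0.0, reject=True, alpha=alpha)
    t = diff / np.sqrt(denom)
    df = denom**2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p), reject=p < alpha, alpha=alpha)


def screen_features(
    features: pd.DataFrame,
    alpha: float = 0.05,
    reference: str = "NM",
) -> pd.DataFrame:
    """Welch p-values of every feature, each impaired group vs. normal.

    ``features`` holds one row per sequence with the 12 feature columns plus
    ``label``. Returns a features x groups table of p-values; a feature
    constant in both groups is flagged degenerate (NaN) with a warning, and a
    missing group drops its column with a warning.
    """
    if "label" not in features:
        raise GaitSilError("features table needs a 'label' column")
    present = set(features["label"])
    if reference not in present:
        raise GaitSilError(f"reference group {reference!r} missing")
    groups = [g for g in CLASS_ORDER if g != reference]
    missing = [g for g in groups if g not in present]
    if missing:
        warnings.warn(f"groups missing from data, omitted: {missing}", stacklevel=2)
        groups = [g for g in groups if g in present]
    if not groups:
        raise GaitSilError("no impaired group present")
    ref = features[features["label"] == reference]
    table = pd.DataFrame(index=list(FEATURE_COLUMNS), columns=groups, dtype=float)
    for feat in FEATURE_COLUMNS:
        for g in groups:
            imp = features[features["label"] == g]
            a = ref[feat].to_numpy(float)
            b = imp[feat].to_numpy(float)
            if a.var() == 0 and b.var() == 0 and a.mean() == b.mean():
                warnings.warn(
                    f"feature {feat!r} constant in {reference} and {g}; excluded",
                    stacklevel=2,
                )
                table.loc[feat, g] = np.nan
                continue
            table.loc[feat, g] = welch_ttest(b, a, alpha=alpha).p
    return table


def train_classifier(
    X,
    y,
    kernel: str = "quadratic",
    C: float = 1.0,
) -> Pipeline:
    """Fit a standardized SVM (one-vs-one multiclass).

    ``kernel="quadratic"`` is a degree-2 polynomial kernel with coef0 = 1;
    ``kernel="linear"`` is provided for comparison. Features are z-scored
    with training-set statistics inside the pipeline, so cross-validation
    cannot leak test-set scale information.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise GaitSilError("training data must contain >=2 classes")
    if kernel == "quadratic":
        svc = SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale", C=C)
    elif kernel == "linear":
        svc = SVC(kernel="linear", C=C)
    else:
        raise GaitSilError(f"unknown kernel {kernel!r}")
    model = Pipeline([("scale", StandardScaler()), ("svm", svc)])
    model.fit(X, y)
    return model


def subject_folds(
    subjects,
    k: int = 5,
    seed: int = 0,
) -> list[list]:
    """Partition sorted unique subject ids into ``k`` groups (seeded shuffle)."""
    uniq = sorted(set(subjects))
    if len(uniq) < k:
        raise GaitSilError(f"{len(uniq)} subjects cannot fill {k} folds")
    order = np.random.default_rng(seed).permutation(len(uniq))
    return [sorted(uniq[i] for i in chunk) for chunk in np.array_split(order, k)]


def cross_validate(
    features: pd.DataFrame,
    k: int = 5,
    kernel: str = "quadratic",
    C: float = 1.0,
    seed: int = 0,
) -> CVResult:
    """Subject-exclusive k-fold cross-validation of the SVM.

    Every fold's test subjects are disjoint from its training subjects (a
    violation is a hard failure). Reports per-fold accuracy, their mean, and
    the pooled true x predicted confusion matrix in FB, RL, LL, NM order.
    """
    for col in ("label", "subject_id"):
        if col not in features:
            raise GaitSilError(f"features table needs a {col!r} column")
    folds = subject_folds(features["subject_id"], k=k, seed=seed)
    X = features.loc[:, list(FEATURE_COLUMNS)].to_numpy(float)
    y = features["label"].to_numpy()
    subj = features["subject_id"].to_numpy()
    cm = np.zeros((len(CLASS_ORDER), len(CLASS_ORDER)), dtype=int)
    accs = []
    for test_subjects in folds:
        test_mask = np.isin(subj, test_subjects)
        train_subjects = set(subj[~test_mask])
        if train_subjects & set(test_subjects):
            raise GaitSilError("subject appears in both train and test split")
        model = train_classifier(X[~test_mask], y[~test_mask], kernel=kernel, C=C)
        pred = model.predict(X[test_mask])
        accs.append(float((pred == y[test_mask]).mean()))
        cm += sk_confusion_matrix(y[test_mask], pred, labels=list(CLASS_ORDER))
    confusion = pd.DataFrame(cm, index=list(CLASS_ORDER), columns=list(CLASS_ORDER))
    return CVResult(
        fold_subjects=folds,
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        confusion=confusion,
    )


def confusion_metrics(cm) -> dict:
    """Recall/precision/accuracy and the goodness index from a 4x4 matrix.

    Per-class recall = diagonal / row sum, precision = diagonal / column sum
    (all-zero columns are excluded from the macro average with a warning);
    macro averages are unweighted class means; the goodness index is
    G = sqrt((1 - macro recall)^2 + (1 - macro precision)^2),
    0 for a perfect classifier.
    """
    if isinstance(cm, pd.DataFrame):
        classes = list(cm.index)
        counts = cm.to_numpy(dtype=float)
    else:
        counts = np.asarray(cm, dtype=float)
        classes = list(CLASS_ORDER[: counts.shape[0]])
    if counts.size == 0 or counts.sum() == 0:
        raise DegenerateInputError("empty confusion matrix")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if np.any(row == 0):
        raise DegenerateInputError("confusion matrix has an empty true class")
    recall = np.diag(counts) / row
    defined = col > 0
    if not defined.all():
        warnings.warn(
            "classes never predicted excluded from macro precision: "
            f"{[c for c, d in zip(classes, defined) if not d]}",
            stacklevel=2,
        )
    precision = np.full(len(classes), np.nan)
    precision[defined] = np.diag(counts)[defined] / col[defined]
    macro_recall = float(recall.mean())
    macro_precision = float(np.nanmean(precision))
    accuracy = float(np.trace(counts) / counts.sum())
    goodness = float(np.hypot(1 - macro_recall, 1 - macro_precision))
    return {
        "classes": classes,
        "recall": dict(zip(classes, recall.tolist())),
        "precision": dict(zip(classes, precision.tolist())),
        "macro_recall": macro_recall,
        "macro_precision": macro_precision,
        "accuracy": accuracy,
        "goodness_index": goodness,
    }
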