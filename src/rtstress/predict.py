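"""Multi-label prediction of during-treatment stress features.

The clinical question: can the seven directional stress labels of the
in-treatment window be predicted from waiting-room information alone?
Eight input datasets are assembled from the seven before-treatment
features plus subsets of {age, sex, day}:

    Type 1: features only            Type 5: + age + sex
    Type 2: + age                    Type 6: + age + day
    Type 3: + sex                    Type 7: + sex + day
    Type 4: + day                    Type 8: + age + sex + day

Models: a single decision tree, a random-forest ensemble, per-label
RBF support-vector machines, and two sequence models (recurrent and
self-attention) that read the z-scored input vector as an ordered
univariate sequence.  Performance is assessed with 10-fold
cross-validation; evaluation reports the exact match ratio (EMR) and
example-based accuracy / recall / precision / F1 (micro-averaged
variants are emitted alongside).  The binary stress call (score > 50%)
is derived from the predicted labels via the scoring rule, never
trained separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import score as score_mod
from ._seqmodels import AttentionNet, RecurrentNet
from .types import FEATURE_ORDER, CaseRecord

__all__ = [
    "DATASET_COVARIATES",
    "MODEL_SPECS",
    "PredictionDataset",
    "EvaluationReport",
    "build_dataset",
    "fit_predict",
    "crossvalidate",
    "evaluate_multilabel",
    "evaluate_binary",
]

DATASET_COVARIATES: dict[int, tuple[str, ...]] = {
    1: (),
    2: ("age",),
    3: ("sex",),
    4: ("day",),
    5: ("age", "sex"),
    6: ("age", "day"),
    7: ("sex", "day"),
    8: ("age", "sex", "day"),
}

MODEL_SPECS = ("tree", "forest", "svm", "rnn", "attention")

#: Models that want per-fold z-scored inputs (trees take raw values).
_SCALED_MODELS = {"svm", "rnn", "attention"}


@dataclass
class PredictionDataset:
    """Inputs, targets and patient groups for one dataset type."""

    dataset_type: int
    X: np.ndarray            # (n, 7 + n_covariates)
    Y: np.ndarray            # (n, 7) boolean targets
    groups: np.ndarray       # patient ids, length n
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        expected = 7 + len(DATASET_COVARIATES[self.dataset_type])
        if self.X.shape[1] != expected:
            raise ValueError(
                f"Type {self.dataset_type} requires input width {expected}"
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class EvaluationReport:
    """Multi-label (or binary) evaluation summary.

    ``emr`` is the fraction of cases whose full label vector is
    correct; ``accuracy``/``recall``/``precision``/``f1`` follow
    ``averaging_mode`` (example-based by default, with micro-averaged
    values in ``micro``).  ``per_fold`` holds one dict per
    cross-validation fold when produced by :func:`crossvalidate`.
    """

    emr: float
    accuracy: float
    recall: float
    precision: float
    f1: float
    averaging_mode: str = "example"
    micro: dict = field(default_factory=dict)
    per_fold: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("emr", "accuracy", "recall", "precision", "f1"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} out of [0, 1]: {v}")


def build_dataset(
    cases: Sequence[CaseRecord], dataset_type: int
) -> PredictionDataset:
    """Assemble inputs/targets for one of the eight dataset types.

    Column order is deterministic: the seven before-treatment features
    in canonical order, then the type's covariates (sex encoded
    M=1/F=0, day as integer).  Undefined LF/HF ratios become 0 (no HF
    variability implies no measurable sympatho-vagal balance shift).
    """
    if dataset_type not in DATASET_COVARIATES:
        raise ValueError("dataset_type must be 1-8")
    covs = DATASET_COVARIATES[dataset_type]
    rows, targets, groups = [], [], []
    for c in cases:
        if c.before is None or c.assessment is None:
            raise ValueError(f"case {c.patient_id} day {c.day} lacks features")
        vec = c.before.vector()
        vec = np.nan_to_num(vec, nan=0.0)
        extra = []
        for cov in covs:
            if cov == "age":
                extra.append(float(c.age))
            elif cov == "sex":
                extra.append(1.0 if c.sex == "M" else 0.0)
            elif cov == "day":
                extra.append(float(c.day))
        rows.append(np.concatenate([vec, extra]))
        targets.append([c.assessment.labels[k] for k in FEATURE_ORDER])
        groups.append(c.patient_id)
    columns = tuple(f"before_{k}" for k in FEATURE_ORDER) + covs
    return PredictionDataset(
        dataset_type=dataset_type,
        X=np.array(rows, dtype=float),
        Y=np.array(targets, dtype=int),
        groups=np.array(groups),
        columns=columns,
    )


class _PerLabelSVM:
    """One RBF SVM per label; constant training labels short-circuit to
    a constant prediction (with a warning)."""

    def __init__(self, seed: int):
        self.seed = seed
        self.models: list = []

    def fit(self, X, Y):
        from sklearn.svm import SVC

        self.models = []
        for j in range(Y.shape[1]):
            col = Y[:, j]
            if np.unique(col).size < 2:
                warnings.warn(
                    f"label column {j} is single-class in training; "
                    "predicting its constant value",
                    UserWarning,
                )
                self.models.append(("const", int(col[0])))
            else:
                m = SVC(kernel="rbf", C=1.0, gamma="scale",
                        random_state=self.seed)
                m.fit(X, col)
                self.models.append(("svm", m))
        return self

    def predict(self, X):
        out = np.empty((X.shape[0], len(self.models)), dtype=int)
        for j, (kind, m) in enumerate(self.models):
            out[:, j] = m if kind == "const" else m.predict(X)
        return out


def _make_model(model_spec: str, seed: int):
    if model_spec == "tree":
        from sklearn.tree import DecisionTreeClassifier

        return DecisionTreeClassifier(random_state=seed)
    if model_spec == "forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if model_spec == "svm":
        return _PerLabelSVM(seed=seed)
    if model_spec == "rnn":
        return RecurrentNet(seed=seed)
    if model_spec == "attention":
        return AttentionNet(seed=seed)
    raise ValueError(
        f"unknown model_spec {model_spec!r}; choose from {MODEL_SPECS}"
    )


def _fold_indices(
    dataset: PredictionDataset, k: int, seed: int, grouped: bool
):
    from sklearn.model_selection import GroupKFold, KFold

    if k > dataset.n:
        raise ValueError(f"k={k} exceeds number of cases ({dataset.n})")
    if grouped:
        splitter = GroupKFold(n_splits=k)
        return list(splitter.split(dataset.X, dataset.Y, dataset.groups))
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(dataset.X))


def _fit_fold(dataset, model_spec, seed, train_idx, test_idx) -> np.ndarray:
    Xtr, Xte = dataset.X[train_idx], dataset.X[test_idx]
    Ytr = dataset.Y[train_idx]
    if model_spec in _SCALED_MODELS:
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
    model = _make_model(model_spec, seed)
    if model_spec in ("tree", "forest") and any(
        np.unique(Ytr[:, j]).size < 2 for j in range(Ytr.shape[1])
    ):
        # sklearn handles constant columns; just surface the degeneracy
        warnings.warn("single-class label column in training fold", UserWarning)
    model.fit(Xtr, Ytr)
    pred = np.asarray(model.predict(Xte))
    return pred.astype(int)


def fit_predict(
    dataset: PredictionDataset,
    model_spec: str,
    seed: int = 0,
    k: int = 10,
    grouped: bool = True,
) -> np.ndarray:
    """Out-of-fold predicted labels for every case.

    Each case is predicted by a model trained on the other folds;
    training is deterministic given the seed.
    """
    folds = _fold_indices(dataset, k, seed, grouped)
    pred = np.zeros_like(dataset.Y)
    for train_idx, test_idx in folds:
        pred[test_idx] = _fit_fold(dataset, model_spec, seed, train_idx, test_idx)
    return pred


def evaluate_multilabel(
    pred: np.ndarray, true: np.ndarray, averaging_mode: str = "example"
) -> EvaluationReport:
    """EMR plus example-based (and micro) multi-label metrics.

    Example-based per-case metrics treat the positive labels as sets:
    accuracy is Jaccard |Y∩Z|/|Y∪Z|, precision |Y∩Z|/|Z|, recall
    |Y∩Z|/|Y|, F1 their harmonic mean, each averaged over cases.  A
    case with no true and no predicted positives counts 1.0
    throughout; an empty denominator with a non-empty counterpart
    counts 0.
    """
    pred = np.asarray(pred, dtype=int)
    true = np.asarray(true, dtype=int)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    n = pred.shape[0]
    inter = np.sum(pred & true, axis=1).astype(float)
    union = np.sum(pred | true, axis=1).astype(float)
    npred = pred.sum(axis=1).astype(float)
    ntrue = true.sum(axis=1).astype(float)

    acc = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    prec = np.where(npred > 0, inter / np.maximum(npred, 1),
                    (ntrue == 0).astype(float))
    rec = np.where(ntrue > 0, inter / np.maximum(ntrue, 1),
                   (npred == 0).astype(float))
    with np.errstate(invalid="ignore"):
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)

    emr = float(np.mean(np.all(pred == true, axis=1)))

    tp = float(np.sum(pred & true))
    fp = float(np.sum(pred & ~true.astype(bool)))
    fn = float(np.sum(~pred.astype(bool) & true))
    tn = float(pred.size - tp - fp - fn)
    micro = {
        "accuracy": (tp + tn) / pred.size,
        "precision": tp / (tp + fp) if tp + fp > 0 else 0.0,
        "recall": tp / (tp + fn) if tp + fn > 0 else 0.0,
    }
    pr, rc = micro["precision"], micro["recall"]
    micro["f1"] = 2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0

    if averaging_mode == "example":
        vals = dict(
            accuracy=float(np.mean(acc)), precision=float(np.mean(prec)),
            recall=float(np.mean(rec)), f1=float(np.mean(f1)),
        )
    elif averaging_mode == "micro":
        vals = {k: micro[k] for k in ("accuracy", "precision", "recall", "f1")}
    else:
        raise ValueError("averaging_mode must be 'example' or 'micro'")
    return EvaluationReport(
        emr=emr, averaging_mode=averaging_mode, micro=micro, **vals
    )


def evaluate_binary(
    pred_labels: np.ndarray, true_labels: np.ndarray
) -> EvaluationReport:
    """Binary stress-call metrics derived from label vectors.

    Each seven-label vector is reduced to its stress score and the
    yes (>50%) / no call; accuracy, recall, precision and F1 are then
    computed on the calls (positive class = stressed).  With positives
    present but none predicted, precision is 0 with a warning.
    """
    pred_labels = np.asarray(pred_labels, dtype=int)
    true_labels = np.asarray(true_labels, dtype=int)
    if pred_labels.shape != true_labels.shape:
        raise ValueError("shape mismatch")

    def calls(mat: np.ndarray) -> np.ndarray:
        out = []
        for row in mat:
            labels = dict(zip(FEATURE_ORDER, (bool(v) for v in row)))
            out.append(score_mod.classify_stress(score_mod.stress_score(labels)))
        return np.array(out, dtype=bool)

    yp, yt = calls(pred_labels), calls(true_labels)
    tp = float(np.sum(yp & yt))
    fp = float(np.sum(yp & ~yt))
    fn = float(np.sum(~yp & yt))
    acc = float(np.mean(yp == yt))
    if yp.sum() == 0 and yt.sum() > 0:
        warnings.warn(
            "no positive predictions with positives present; precision "
            "defined as 0",
            UserWarning,
        )
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    rec = tp / (tp + fn) if tp + fn > 0 else (1.0 if yp.sum() == 0 else 0.0)
    f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    return EvaluationReport(
        emr=acc, accuracy=acc, recall=rec, precision=prec, f1=f1,
        averaging_mode="binary",
    )


def crossvalidate(
    dataset: PredictionDataset,
    model_spec: str,
    k: int = 10,
    seed: int = 0,
    grouped: bool = True,
) -> tuple[EvaluationReport, EvaluationReport]:
    """K-fold cross-validated multi-label and binary reports.

    Returns ``(multilabel_report, binary_report)``.  The multilabel
    report carries per-fold metric dicts and fold-mean headline
    metrics; the binary report is computed on the pooled out-of-fold
    predictions (each case predicted exactly once).
    """
    folds = _fold_indices(dataset, k, seed, grouped)
    pred = np.zeros_like(dataset.Y)
    per_fold = []
    for train_idx, test_idx in folds:
        p = _fit_fold(dataset, model_spec, seed, train_idx, test_idx)
        pred[test_idx] = p
        rep = evaluate_multilabel(p, dataset.Y[test_idx])
        per_fold.append(
            {m: getattr(rep, m)
             for m in ("emr", "accuracy", "recall", "precision", "f1")}
        )
    means = {
        m: float(np.mean([f[m] for f in per_fold]))
        for m in ("emr", "accuracy", "recall", "precision", "f1")
    }
    pooled = evaluate_multilabel(pred, dataset.Y)
    report = EvaluationReport(
        averaging_mode="example", micro=pooled.micro, per_fold=per_fold, **means
    )
    binary = evaluate_binary(pred, dataset.Y)
    return report, binary
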