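"""Three-class survival classification under nested stratified CV.

The classifier is a feed-forward network with 3 hidden layers of 8 neurons
(softmax output, cross-entropy loss), the architecture used throughout this
pipeline.  Training follows a nested stratified scheme: a global stratified
holdout (10 subjects by default) is reserved untouched; the remainder is
split into stratified outer folds; inside each outer training set an inner
stratified CV selects the weight-decay strength; one member model per outer
fold is refit on the full outer training set.  Out-of-fold predictions from
the outer loop give the cross-validation accuracy, the member models applied
to the holdout give the holdout accuracy, and averaging the members' class
scores gives the ensemble prediction.

Feature scaling (zero mean / unit variance) is computed from each fold's
training subjects only; the binary sex code passes through unscaled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier

from .encoder import AutoencoderModel, encode
from .errors import SchemaError, ShapeError, StratificationError
from .synthetic import CLASSES, Cohort

#: Prognosis-ordered class labels; index 0 is the worst prognosis, which is
#: also the tie-break winner in averaged-mode prediction.
CLASS_ORDER: tuple[str, ...] = CLASSES


@dataclass
class ClassifierConfig:
    hidden_layers: tuple[int, int, int] = (8, 8, 8)
    outer_folds: int = 10
    inner_folds: int = 5
    holdout_size: int = 10
    #: weight-decay grid searched by the inner loop; a single entry (or
    #: inner_folds < 2) disables the inner search
    alpha_grid: tuple[float, ...] = (1e-4, 1e-2)
    learning_rate_init: float = 0.03
    max_iter: int = 500
    n_iter_no_change: int = 20
    #: with ``use_validation_stopping`` the stop rule watches a held-out
    #: score; otherwise it watches the training loss, which is far more
    #: stable at the fold sizes this pipeline sees
    use_validation_stopping: bool = False
    validation_fraction: float = 0.15


@dataclass
class EnsembleMember:
    model: MLPClassifier
    fold_id: int
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    alpha: float


@dataclass
class TrainedEnsemble:
    members: list[EnsembleMember]
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    cv_predictions: pd.Series  # out-of-fold predicted class per non-holdout subject
    cv_labels: pd.Series
    holdout_ids: tuple[str, ...]
    fold_test_ids: dict[int, tuple]  # fold id -> its out-of-fold subject ids
    config: ClassifierConfig


@dataclass
class AccuracyReport:
    cv_accuracy: float
    holdout_accuracy: float
    combined_accuracy: float
    ensemble_accuracy: float
    n_cv: int
    n_holdout: int
    confusion: dict[str, np.ndarray]
    #: holdout accuracy per member, whose mean equals the pooled
    #: model-by-subject holdout accuracy when every member scores every
    #: holdout subject
    holdout_accuracy_by_member: tuple[float, ...] = ()


def assemble_features(
    cohort: Cohort | pd.DataFrame,
    connectomes: pd.DataFrame,
    encoder_model: AutoencoderModel,
) -> tuple[pd.DataFrame, pd.Series]:
    """Join demographics, cortical thickness and encoded FC per subject.

    Returns one row per cohort subject (cohort order) with columns
    age, sex, ct_01..ct_34, FC1..FCm, plus the survival-class labels.
    """
    table = cohort.to_frame() if isinstance(cohort, Cohort) else cohort.copy()
    table = table.set_index("subject_id")
    if len(table) == 0:
        cols = ["age", "sex"] + [f"ct_{i:02d}" for i in range(1, 35)] \
            + encoder_model.feature_names
        return pd.DataFrame(columns=cols), pd.Series(dtype=object, name="survival_class")
    missing = [sid for sid in table.index if sid not in connectomes.index]
    if missing:
        raise SchemaError(f"subjects missing from connectome table: {missing}")
    conn = connectomes.loc[table.index]
    codes = encode(encoder_model, conn.to_numpy(float))
    fc = pd.DataFrame(codes, index=table.index, columns=encoder_model.feature_names)
    ct_cols = [c for c in table.columns if c.startswith("ct_")]
    X = pd.concat([table[["age", "sex"]], table[ct_cols], fc], axis=1)
    y = table["survival_class"].rename("survival_class")
    return X, y


def _scale_stats(X: np.ndarray, sex_col: int | None) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    if sex_col is not None:
        mean[sex_col] = 0.0
        sd[sex_col] = 1.0
    return mean, sd


def _fit_member(Xtr, ytr, config: ClassifierConfig, alpha: float, seed: int) -> MLPClassifier:
    clf = MLPClassifier(
        hidden_layer_sizes=config.hidden_layers,
        activation="relu",
        solver="adam",
        alpha=alpha,
        learning_rate_init=config.learning_rate_init,
        max_iter=config.max_iter,
        early_stopping=config.use_validation_stopping,
        validation_fraction=config.validation_fraction,
        n_iter_no_change=config.n_iter_no_change,
        random_state=seed,
    )
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(Xtr, ytr)
    return clf


def _inner_select_alpha(Xtr, ytr, config: ClassifierConfig, rng: np.random.Generator) -> float:
    if len(config.alpha_grid) == 1 or config.inner_folds < 2:
        return config.alpha_grid[0]
    _, counts = np.unique(ytr, return_counts=True)
    n_inner = min(config.inner_folds, counts.min())
    if n_inner < 2:
        return config.alpha_grid[0]
    skf = StratifiedKFold(n_splits=n_inner, shuffle=True,
                          random_state=int(rng.integers(2**31 - 1)))
    scores = []
    for alpha in config.alpha_grid:
        correct = 0
        for tr, te in skf.split(Xtr, ytr):
            clf = _fit_member(Xtr[tr], ytr[tr], config, alpha,
                              seed=int(rng.integers(2**31 - 1)))
            correct += int(np.sum(clf.predict(Xtr[te]) == ytr[te]))
        scores.append(correct)
    return config.alpha_grid[int(np.argmax(scores))]


def train_nested_cv(
    X: pd.DataFrame,
    y: pd.Series,
    config: ClassifierConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> TrainedEnsemble:
    """Nested stratified cross-validation with a global stratified holdout."""
    if config is None:
        config = ClassifierConfig()
    rng = np.random.default_rng(rng)
    if not X.index.equals(y.index):
        raise SchemaError("feature matrix and labels are indexed differently")

    ids = X.index.to_numpy()
    labels = y.to_numpy()
    if config.holdout_size > 0:
        work_ids, holdout_ids = train_test_split(
            ids,
            test_size=config.holdout_size,
            stratify=labels,
            random_state=int(rng.integers(2**31 - 1)),
        )
    else:
        work_ids, holdout_ids = ids, np.array([], dtype=ids.dtype)

    y_work = y.loc[work_ids].to_numpy()
    _, counts = np.unique(y_work, return_counts=True)
    if len(counts) < 3 or counts.min() < 3:
        raise StratificationError(
            "need at least 3 subjects per class after holdout removal; "
            f"got class counts {counts.tolist()}"
        )
    if counts.min() < config.outer_folds:
        raise StratificationError(
            f"smallest class has {counts.min()} members, fewer than "
            f"{config.outer_folds} outer folds"
        )

    sex_pos = X.columns.get_loc("sex") if "sex" in X.columns else None
    Xw = X.loc[work_ids].to_numpy(float)

    skf = StratifiedKFold(n_splits=config.outer_folds, shuffle=True,
                          random_state=int(rng.integers(2**31 - 1)))
    members: list[EnsembleMember] = []
    oof_pred = pd.Series(index=pd.Index(work_ids, name="subject_id"), dtype=object)
    fold_test_ids: dict[int, tuple] = {}
    for fold_id, (tr, te) in enumerate(skf.split(Xw, y_work)):
        mean, sd = _scale_stats(Xw[tr], sex_pos)
        Xtr = (Xw[tr] - mean) / sd
        Xte = (Xw[te] - mean) / sd
        alpha = _inner_select_alpha(Xtr, y_work[tr], config, rng)
        clf = _fit_member(Xtr, y_work[tr], config, alpha,
                          seed=int(rng.integers(2**31 - 1)))
        oof_pred.iloc[te] = clf.predict(Xte)
        fold_test_ids[fold_id] = tuple(work_ids[te].tolist())
        members.append(EnsembleMember(model=clf, fold_id=fold_id,
                                      scale_mean=mean, scale_sd=sd, alpha=alpha))

    return TrainedEnsemble(
        members=members,
        classes=CLASS_ORDER,
        feature_names=tuple(X.columns),
        cv_predictions=oof_pred,
        cv_labels=y.loc[work_ids],
        holdout_ids=tuple(holdout_ids.tolist()),
        fold_test_ids=fold_test_ids,
        config=config,
    )


def _member_proba(member: EnsembleMember, X: np.ndarray,
                  classes: Sequence[str]) -> np.ndarray:
    """Class probabilities in prognosis order (worst first)."""
    Xs = (X - member.scale_mean) / member.scale_sd
    proba = member.model.predict_proba(Xs)
    out = np.zeros((X.shape[0], len(classes)))
    for j, cls in enumerate(member.model.classes_):
        out[:, list(classes).index(cls)] = proba[:, j]
    return out


def predict(
    ensemble: TrainedEnsemble,
    X: pd.DataFrame,
    mode: str = "averaged",
) -> tuple[np.ndarray, np.ndarray]:
    """Predict classes; ``mode`` is ``"per-model"`` or ``"averaged"``.

    Per-model mode returns an (n_members, n_subjects) label array and the
    stacked score tensor; averaged mode returns one label per subject from
    the argmax of the member-mean score vector, ties resolved toward the
    worst prognosis.
    """
    if tuple(X.columns) != ensemble.feature_names:
        raise ShapeError("feature columns do not match the trained ensemble")
    Xa = X.to_numpy(float)
    scores = np.stack([_member_proba(m, Xa, ensemble.classes)
                       for m in ensemble.members])
    cls = np.asarray(ensemble.classes)
    if mode == "per-model":
        labels = cls[np.argmax(scores, axis=2)]
        return labels, scores
    if mode == "averaged":
        mean_scores = scores.mean(axis=0)
        # np.argmax takes the first maximum, and index 0 is the worst
        # prognosis, so ties already break conservatively
        labels = cls[np.argmax(mean_scores, axis=1)]
        return labels, mean_scores
    raise ValueError(f"unknown prediction mode {mode!r}")


def evaluate(ensemble: TrainedEnsemble, X: pd.DataFrame, y: pd.Series) -> AccuracyReport:
    """Accuracy of the trained ensemble on its own experiment.

    Cross-validation accuracy uses the stored out-of-fold predictions;
    holdout accuracy pools every member's prediction on every holdout
    subject; combined accuracy counts cross-validation and holdout subjects
    together; ensemble accuracy scores the averaged-mode prediction on the
    holdout.
    """
    overlap = set(ensemble.cv_predictions.index) & set(ensemble.holdout_ids)
    if overlap:
        raise SchemaError(f"holdout subjects leaked into cross-validation: {sorted(overlap)}")

    y_cv = ensemble.cv_labels
    pred_cv = ensemble.cv_predictions
    correct_cv = int((pred_cv == y_cv).sum())
    n_cv = len(y_cv)
    cv_acc = correct_cv / n_cv if n_cv else float("nan")
    confusion = {
        "cv": confusion_matrix(y_cv, pred_cv, labels=list(ensemble.classes)),
    }

    if ensemble.holdout_ids:
        Xh = X.loc[list(ensemble.holdout_ids)]
        yh = y.loc[list(ensemble.holdout_ids)].to_numpy()
        per_model_labels, _ = predict(ensemble, Xh, mode="per-model")
        by_member = tuple(float(np.mean(row == yh)) for row in per_model_labels)
        holdout_acc = float(np.mean(per_model_labels == yh[None, :]))
        ens_labels, _ = predict(ensemble, Xh, mode="averaged")
        ens_acc = float(np.mean(ens_labels == yh))
        n_holdout = len(yh)
        combined = (correct_cv + holdout_acc * n_holdout) / (n_cv + n_holdout)
        confusion["holdout"] = confusion_matrix(
            np.tile(yh, len(ensemble.members)), per_model_labels.ravel(),
            labels=list(ensemble.classes))
        confusion["ensemble"] = confusion_matrix(
            yh, ens_labels, labels=list(ensemble.classes))
    else:
        by_member = ()
        holdout_acc = float("nan")
        ens_acc = float("nan")
        n_holdout = 0
        combined = cv_acc

    return AccuracyReport(
        cv_accuracy=cv_acc,
        holdout_accuracy=holdout_acc,
        combined_accuracy=combined,
        ensemble_accuracy=ens_acc,
        n_cv=n_cv,
        n_holdout=n_holdout,
        confusion=confusion,
        holdout_accuracy_by_member=by_member,
    )
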