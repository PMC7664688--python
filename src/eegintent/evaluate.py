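"""Subject-wise leave-one-question-out cross-validation.

For the intent task the question universe is a subject's insider-threat
questions (labels: yes/no answer); for the scenario-type task it is all
questions (labels: insider/conflict).  Per fold, the scaler is fitted and the
feature selector run on training-fold epochs only, the classifier is tuned by
question-grouped internal validation, and the held-out question is predicted
by majority vote over its epochs (ties go to the negative class).  Question
scores (positive-epoch fractions) feed the ROC summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import GroupKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from eegintent.features import apply_scaler, feature_columns, fit_scaler
from eegintent.seeding import STAGE, child_seed
from eegintent.selection import BorutaConfig, VarSelRFConfig, boruta_select, varselrf_select

TASKS = ("intent", "scenario_type")
POSITIVE = {"intent": "yes", "scenario_type": "insider"}
NEGATIVE = {"intent": "no", "scenario_type": "conflict"}
LABEL_COLUMN = {"intent": "answer", "scenario_type": "scenario_type"}


def normalize_task(task: str) -> str:
    t = {"scenario": "scenario_type"}.get(task, task)
    if t not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS} (or 'scenario')")
    return t


# ---------------------------------------------------------------- splits

@dataclass(frozen=True)
class CVSplit:
    task: str
    test_question: int
    train_questions: tuple[int, ...]


def make_loqo_splits(subject_table: pd.DataFrame, task: str) -> list[CVSplit]:
    """One split per question; folds with a single-class training side are
    skipped with a warning (never silently dropped)."""
    task = normalize_task(task)
    tbl = subject_table
    if task == "intent":
        tbl = tbl[tbl["scenario_type"] == "insider"]
    label_col = LABEL_COLUMN[task]
    q_labels = (
        tbl[["question", label_col]].drop_duplicates().set_index("question")[label_col]
    )
    questions = sorted(q_labels.index)
    if len(questions) < 2:
        raise ValueError("need at least 2 questions to cross-validate")
    splits: list[CVSplit] = []
    for q in questions:
        train = tuple(p for p in questions if p != q)
        train_classes = set(q_labels.loc[list(train)])
        if len(train_classes) < 2:
            warnings.warn(
                f"fold for question {q}: training side has a single class "
                f"{train_classes}; fold skipped",
                stacklevel=2,
            )
            continue
        splits.append(CVSplit(task=task, test_question=int(q), train_questions=train))
    return splits


# ---------------------------------------------------------------- classifiers

@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family with its hyperparameter tuning grid."""

    family: str  # "knn" | "svm_rbf" | "nb" | "mlp"
    grid: tuple[dict, ...] = ()

    def candidates(self) -> tuple[dict, ...]:
        return self.grid if self.grid else ({},)


def default_classifiers() -> dict[str, ClassifierSpec]:
    """The four families with their default tuning grids."""
    return {
        "knn": ClassifierSpec(
            "knn", tuple({"n_neighbors": k} for k in (1, 3, 5, 7, 9))
        ),
        "svm_rbf": ClassifierSpec(
            "svm_rbf",
            tuple(
                {"C": C, "gamma": g}
                for C in (0.1, 1.0, 10.0, 100.0, 1000.0)
                for g in (1e-4, 1e-3, 1e-2, 1e-1, 1.0)
            ),
        ),
        "nb": ClassifierSpec("nb"),
        "mlp": ClassifierSpec(
            "mlp", tuple({"hidden_layer_sizes": (w,)} for w in (5, 10, 20))
        ),
    }


def build_estimator(family: str, params: dict, seed: int):
    if family == "knn":
        return KNeighborsClassifier(**params)
    if family == "svm_rbf":
        return SVC(kernel="rbf", **params)
    if family == "nb":
        return GaussianNB(**params)
    if family == "mlp":
        return MLPClassifier(max_iter=300, random_state=seed, **params)
    raise ValueError(f"unknown classifier family {family!r}")


@dataclass
class TrainedModel:
    estimator: object
    family: str
    chosen_params: dict
    tuning_scores: dict = field(default_factory=dict)


def train_classifier(
    spec: ClassifierSpec, X_train: np.ndarray, y_train: np.ndarray, groups, seed: int
) -> TrainedModel:
    """Grid search with question-grouped internal validation.

    Epochs of one question never straddle tuning folds.  Ties break to the
    first grid entry, so the choice is deterministic given seed.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    groups = np.asarray(groups)
    candidates = list(spec.candidates())
    if not candidates:
        raise ValueError("empty tuning grid")
    # kNN cannot use more neighbors than training rows
    if spec.family == "knn":
        candidates = [c for c in candidates if c.get("n_neighbors", 1) <= len(y_train)]
        if not candidates:
            candidates = [{"n_neighbors": 1}]

    scores: dict[int, float] = {}
    n_groups = len(np.unique(groups))
    if len(candidates) > 1 and n_groups >= 2:
        n_splits = min(3, n_groups)
        gkf = GroupKFold(n_splits=n_splits)
        folds = list(gkf.split(X_train, y_train, groups))
        for ci, params in enumerate(candidates):
            accs = []
            for tr, va in folds:
                if len(np.unique(y_train[tr])) < 2:
                    continue
                est = build_estimator(spec.family, params, seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X_train[tr], y_train[tr])
                accs.append(float((est.predict(X_train[va]) == y_train[va]).mean()))
            scores[ci] = float(np.mean(accs)) if accs else -np.inf
        best = max(range(len(candidates)), key=lambda ci: (scores[ci], -ci))
    else:
        best = 0
    params = candidates[best]
    est = build_estimator(spec.family, params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X_train, y_train)
    return TrainedModel(
        estimator=est,
        family=spec.family,
        chosen_params=params,
        tuning_scores={tuple(sorted(candidates[k].items())): v for k, v in scores.items()},
    )


# ---------------------------------------------------------------- voting

def predict_question(model, epoch_features: np.ndarray, positive, negative):
    """Majority vote over a question's epochs.

    Returns (label, score) with score the positive-epoch fraction; a tied
    vote predicts the negative class.
    """
    epoch_features = np.asarray(epoch_features, dtype=float)
    if epoch_features.shape[0] == 0:
        raise ValueError("question has no epochs to predict")
    est = model.estimator if isinstance(model, TrainedModel) else model
    preds = est.predict(epoch_features)
    score = float(np.mean(preds == positive))
    label = positive if score > 0.5 else negative
    return label, score


# ---------------------------------------------------------------- subject CV

@dataclass
class QuestionPrediction:
    question: int
    true: str
    pred: str
    score: float
    n_epochs: int
    chosen_params: dict = field(default_factory=dict)
    n_selected: int = 0


@dataclass
class SubjectResult:
    subject: str
    task: str
    selector: str
    classifier: str
    predictions: list[QuestionPrediction] = field(default_factory=list)
    skipped_questions: list[int] = field(default_factory=list)
    audit: list[dict] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        if not self.predictions:
            raise ValueError(f"subject {self.subject} has no evaluable folds")
        return float(np.mean([p.pred == p.true for p in self.predictions]))

    @property
    def scores_and_labels(self) -> tuple[np.ndarray, np.ndarray]:
        s = np.array([p.score for p in self.predictions])
        t = np.array([p.true for p in self.predictions])
        return s, t


def _make_selector(name_or_fn, boruta_config, varselrf_config):
    if callable(name_or_fn):
        return name_or_fn
    if name_or_fn == "none":
        return lambda X, y, seed: list(X.columns)
    if name_or_fn == "boruta":
        return lambda X, y, seed: boruta_select(X, y, boruta_config, seed).selected
    if name_or_fn == "varselrf":
        return lambda X, y, seed: varselrf_select(X, y, varselrf_config, seed)
    raise ValueError(f"unknown selector {name_or_fn!r}")


def run_subject_cv_cells(
    subject_table: pd.DataFrame,
    task: str,
    selectors: dict,
    classifiers: dict[str, ClassifierSpec],
    seed: int,
    boruta_config: BorutaConfig | None = None,
    varselrf_config: VarSelRFConfig | None = None,
) -> dict[tuple[str, str], SubjectResult]:
    """Leave-one-question-out CV for every selector x classifier cell.

    Selection runs once per (fold, selector) and is shared across classifiers;
    the scaler, selector, and tuner see training-fold rows only, and the audit
    trail records the exact row sets each saw.
    """
    task = normalize_task(task)
    subjects = subject_table["subject"].unique()
    if len(subjects) != 1:
        raise ValueError("run_subject_cv_cells expects a single subject's table")
    subject = str(subjects[0])
    label_col = LABEL_COLUMN[task]
    positive, negative = POSITIVE[task], NEGATIVE[task]

    tbl = subject_table.reset_index(drop=True)
    if task == "intent":
        tbl = tbl[tbl["scenario_type"] == "insider"].reset_index(drop=True)
    splits = make_loqo_splits(tbl, task)

    results = {
        (sn, cn): SubjectResult(subject, task, sn, cn)
        for sn in selectors for cn in classifiers
    }
    all_questions = set(tbl["question"])
    evaluated = {s.test_question for s in splits}
    for (sn, cn), res in results.items():
        res.skipped_questions = sorted(all_questions - evaluated)

    feat_cols = feature_columns(tbl)
    for fold_idx, split in enumerate(splits):
        train_mask = tbl["question"].isin(split.train_questions)
        test_mask = tbl["question"] == split.test_question
        train_rows = tbl.index[train_mask]
        test_rows = tbl.index[test_mask]
        assert len(set(train_rows) & set(test_rows)) == 0
        assert split.test_question not in split.train_questions

        train = tbl.loc[train_rows]
        test = tbl.loc[test_rows]
        scaler = fit_scaler(train, feat_cols)
        train_s = apply_scaler(scaler, train)
        test_s = apply_scaler(scaler, test)
        y_train = train_s[label_col].to_numpy()
        groups = train_s["question"].to_numpy()

        sel_cache: dict[str, list] = {}
        for sn, sel in selectors.items():
            fn = _make_selector(sel, boruta_config, varselrf_config)
            cols = fn(
                train_s[feat_cols], y_train,
                child_seed(seed, STAGE["selection"], fold_idx, _stable_tag(sn)),
            )
            if not cols:
                cols = list(feat_cols)  # degenerate selection: keep everything
            sel_cache[sn] = list(cols)

        for cn, spec in classifiers.items():
            for sn in selectors:
                cols = sel_cache[sn]
                model = train_classifier(
                    spec,
                    train_s[cols].to_numpy(),
                    y_train,
                    groups,
                    child_seed(seed, STAGE["classifier"], fold_idx,
                               _stable_tag(sn), _stable_tag(cn)),
                )
                label, score = predict_question(
                    model, test_s[cols].to_numpy(), positive, negative
                )
                res = results[(sn, cn)]
                res.predictions.append(
                    QuestionPrediction(
                        question=split.test_question,
                        true=str(test[label_col].iloc[0]),
                        pred=str(label),
                        score=score,
                        n_epochs=int(test_mask.sum()),
                        chosen_params=model.chosen_params,
                        n_selected=len(cols),
                    )
                )
                res.audit.append(
                    {
                        "fold": fold_idx,
                        "train_rows": [int(i) for i in train_rows],
                        "test_rows": [int(i) for i in test_rows],
                        "train_questions": list(split.train_questions),
                        "test_question": split.test_question,
                    }
                )
    return results


def _stable_tag(name: str) -> int:
    """Deterministic small integer for a stage/selector/classifier name."""
    return sum((i + 1) * ord(c) for i, c in enumerate(str(name))) % 100003


def run_subject_cv(
    subject_table: pd.DataFrame,
    task: str,
    selector,
    classifier_spec: ClassifierSpec,
    seed: int,
    **kwargs,
) -> SubjectResult:
    """Single selector x classifier cell; see :func:`run_subject_cv_cells`."""
    cells = run_subject_cv_cells(
        subject_table, task, {"selector": selector},
        {"classifier": classifier_spec}, seed, **kwargs
    )
    return cells[("selector", "classifier")]


# ---------------------------------------------------------------- summaries

def aggregate_summary(
    results: dict[tuple[str, str], list[SubjectResult]]
) -> pd.DataFrame:
    """Mean accuracy (%) per selector x classifier cell over subjects."""
    selectors = sorted({k[0] for k in results})
    classifiers = sorted({k[1] for k in results})
    table = pd.DataFrame(index=selectors, columns=classifiers, dtype=float)
    for (sn, cn), subject_results in results.items():
        evaluable = [r for r in subject_results if r.predictions]
        if not evaluable:
            raise ValueError(f"no evaluable subjects for cell ({sn}, {cn})")
        table.loc[sn, cn] = 100.0 * float(np.mean([r.accuracy for r in evaluable]))
    table.index.name = "selector"
    return table


def roc_points(question_scores, labels, positive) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC over question scores: (fpr, tpr, thresholds, trapezoidal AUC)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    y = (labels == positive).astype(int)
    fpr, tpr, thr = roc_curve(y, np.asarray(question_scores, dtype=float))
    return fpr, tpr, thr, float(sk_auc(fpr, tpr))


def pooled_roc(results: list[SubjectResult], positive) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC over all subjects' question scores pooled together."""
    scores = np.concatenate([r.scores_and_labels[0] for r in results])
    labels = np.concatenate([r.scores_and_labels[1] for r in results])
    return roc_points(scores, labels, positive)


# ---------------------------------------------------------------- experiment level

def evaluate_experiment(
    table: pd.DataFrame,
    task: str,
    selectors: dict,
    classifiers: dict[str, ClassifierSpec],
    seed: int,
    boruta_config: BorutaConfig | None = None,
    varselrf_config: VarSelRFConfig | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], list[SubjectResult]]]:
    """Run every subject's CV and aggregate the selector x classifier table."""
    task = normalize_task(task)
    results: dict[tuple[str, str], list[SubjectResult]] = {
        (sn, cn): [] for sn in selectors for cn in classifiers
    }
    for si, subject in enumerate(sorted(table["subject"].unique())):
        sub = table[table["subject"] == subject]
        try:
            cells = run_subject_cv_cells(
                sub, task, selectors, classifiers,
                child_seed(seed, 7, si),
                boruta_config=boruta_config, varselrf_config=varselrf_config,
            )
        except ValueError:
            warnings.warn(f"subject {subject}: unevaluable for task {task}; skipped",
                          stacklevel=2)
            continue
        for key, res in cells.items():
            if res.predictions:
                results[key].append(res)
    summary = aggregate_summary(results)
    return summary, results


def subset_feature_table(table: pd.DataFrame, channels) -> pd.DataFrame:
    """Restrict a feature table to the columns of the named channels."""
    from eegintent.channels import validate_channels
    from eegintent.features import METADATA_COLUMNS, feature_column_names

    validate_channels(channels)
    cols = [c for c in feature_column_names(channels) if c in table.columns]
    missing = set(feature_column_names(channels)) - set(cols)
    if missing:
        raise ValueError(f"table lacks columns for requested channels: {sorted(missing)[:5]} ...")
    return table[[c for c in METADATA_COLUMNS if c in table.columns] + cols]


def channel_subset_run(
    table: pd.DataFrame,
    channels,
    task: str,
    selectors: dict,
    classifiers: dict[str, ClassifierSpec],
    seed: int,
    **kwargs,
) -> tuple[pd.DataFrame, dict[tuple[str, str], list[SubjectResult]]]:
    """The identical pipeline restricted to a channel subset's feature columns."""
    sub = subset_feature_table(table, channels)
    return evaluate_experiment(sub, task, selectors, classifiers, seed, **kwargs)
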