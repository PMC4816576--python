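"""Balanced RBF-SVM classification of response correctness.

Within-task decoding runs a stratified 10-fold cross-validation on the
balanced feature set, with the SVM hyperparameters (C, γ) chosen by a
nested grid search: a coarse search over powers of two followed by a finer
half-power search around the coarse optimum.  Across-task decoding trains
on one task (with the hyperparameters established on that task) and tests
on the balanced trials of the other.  Significance comes from a label
randomisation test, and the whole scheme is repeated with freshly drawn
correct-trial samples, reporting mean/min/max aggregates.

The scaler is fit on the training partition only and applied with clipping
to held-out or transfer data; the error class is the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .epochs import Epochs
from .features import (
    FeatureMatrix,
    FeatureSetSpec,
    apply_scaler,
    balance_classes,
    extract_features,
    fit_scaler,
)

__all__ = [
    "SvmParams",
    "GridSearchResult",
    "RepeatResult",
    "ClassificationReport",
    "MODES",
    "accuracy_rate",
    "train_svm",
    "cv_accuracy",
    "nested_grid_search",
    "transfer_classify",
    "permutation_pvalue",
    "repeat_and_aggregate",
]

MODES = (
    "within-flanker",
    "within-rotation",
    "flanker-to-rotation",
    "rotation-to-flanker",
)

# coarse grid: C in 2^-5 .. 2^15, gamma in 2^-15 .. 2^3, step 2^2
COARSE_C_EXPONENTS = tuple(range(-5, 16, 2))
COARSE_GAMMA_EXPONENTS = tuple(range(-15, 4, 2))
FINE_HALF_SPAN = 2.0  # powers of two around the coarse optimum
FINE_STEP = 0.5


@dataclass(frozen=True)
class SvmParams:
    """RBF-SVM hyperparameters."""

    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be > 0")


DEFAULT_PARAMS = SvmParams(C=1.0, gamma=0.1)


@dataclass
class GridSearchResult:
    coarse: list[tuple[SvmParams, float]]
    fine: list[tuple[SvmParams, float]]
    selected: SvmParams
    selected_cv_accuracy: float  # %
    selected_n_correct: int
    n_total: int

    @property
    def evaluated(self) -> list[tuple[SvmParams, float]]:
        return self.coarse + self.fine


@dataclass(frozen=True)
class RepeatResult:
    """One repeat of the analysis scheme."""

    repeat: int
    accuracy: float  # %
    p: float
    n_correct: int
    n_total: int
    params: SvmParams

    def __post_init__(self) -> None:
        expected = accuracy_rate(self.n_correct, self.n_total)
        if abs(expected - self.accuracy) > 1e-9:
            raise ValueError("accuracy must equal 100 * n_correct / n_total")
        if not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")


@dataclass
class ClassificationReport:
    """Per-subject, per-feature-set, per-mode record of the repeated analyses."""

    subject: int
    feature_set: str
    mode: str
    repeats: list[RepeatResult]

    def _agg(self, attr: str) -> tuple[float, float, float]:
        vals = np.array([getattr(r, attr) for r in self.repeats], dtype=float)
        return float(vals.mean()), float(vals.min()), float(vals.max())

    @property
    def accuracy_mean_min_max(self):
        return self._agg("accuracy")

    @property
    def p_mean_min_max(self):
        return self._agg("p")

    @property
    def trials_correct_mean_min_max(self):
        return self._agg("n_correct")

    @property
    def trials_total(self) -> int:
        totals = {r.n_total for r in self.repeats}
        if len(totals) != 1:
            raise ValueError("repeats disagree on the analysis-set size")
        return totals.pop()


def accuracy_rate(n_correct: int, n_total: int) -> float:
    """Percentage of correct classification incidents."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_correct <= n_total:
        raise ValueError("n_correct must lie in [0, n_total]")
    return 100.0 * n_correct / n_total


def _as_binary(labels: np.ndarray) -> np.ndarray:
    """Error = positive class (1)."""
    return (np.asarray(labels) == "error").astype(int)


def train_svm(features: FeatureMatrix, params: SvmParams) -> SVC:
    """Fit a soft-margin RBF-SVM on a scaled feature matrix."""
    if not features.scaled:
        raise ValueError("features must be scaled before training")
    y = _as_binary(features.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    clf = SVC(C=params.C, gamma=params.gamma, kernel="rbf")
    clf.fit(features.values, y)
    return clf


def _cv_counts(
    features: FeatureMatrix,
    labels,
    params: SvmParams,
    k: int,
    seed: int,
    scale_jointly: bool = False,
) -> tuple[int, int]:
    """Pooled (n_correct, n_total) over all held-out trials of a stratified k-fold.

    Per fold the scaler and the SVM are fit on the training part only;
    ``scale_jointly`` instead fits the scaler once on the whole analysis set
    (a leakier recipe kept as a compatibility switch).
    """
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if k > features.n_trials:
        raise ValueError("more folds than trials")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % 2**32)
    x = features.values
    joint_scaler = fit_scaler(features) if scale_jointly else None
    n_correct = 0
    for train_idx, test_idx in skf.split(x, y):
        train = FeatureMatrix(x[train_idx], features.feature_names, np.asarray(labels)[train_idx])
        scaler = joint_scaler if scale_jointly else fit_scaler(train)
        clf = train_svm(apply_scaler(train, scaler), params)
        test = apply_scaler(
            FeatureMatrix(x[test_idx], features.feature_names, np.asarray(labels)[test_idx]),
            scaler,
        )
        n_correct += int(np.sum(clf.predict(test.values) == y[test_idx]))
    return n_correct, features.n_trials


def cv_accuracy(
    features: FeatureMatrix,
    labels,
    params: SvmParams,
    k: int = 10,
    seed: int = 0,
    scale_jointly: bool = False,
) -> float:
    """Pooled stratified k-fold CV accuracy (%) at fixed hyperparameters."""
    n_correct, n_total = _cv_counts(features, labels, params, k, seed, scale_jointly)
    return accuracy_rate(n_correct, n_total)


def _grid(points_c, points_gamma) -> list[SvmParams]:
    return [
        SvmParams(C=2.0**ce, gamma=2.0**ge)
        for ce in points_c
        for ge in points_gamma
    ]


def nested_grid_search(
    features: FeatureMatrix, labels, k: int = 10, seed: int = 0, scale_jointly: bool = False
) -> GridSearchResult:
    """Coarse-then-fine (C, γ) search maximising the k-fold CV accuracy.

    The fine grid spans ±2 powers of two around the coarse optimum in steps
    of 2^0.5.  The selected pair maximises CV accuracy over everything
    evaluated; exact ties go to the smallest C, then the smallest γ.  Folds
    are identical across grid points (same seed).
    """
    def evaluate(params_list):
        out = []
        for params in params_list:
            n_corr, n_tot = _cv_counts(features, labels, params, k, seed, scale_jointly)
            out.append((params, accuracy_rate(n_corr, n_tot), n_corr, n_tot))
        return out

    coarse = evaluate(_grid(COARSE_C_EXPONENTS, COARSE_GAMMA_EXPONENTS))
    best_c, best_acc = None, -1.0
    for params, acc, *_ in coarse:
        if acc > best_acc:
            best_c, best_acc = params, acc
    ce0, ge0 = np.log2(best_c.C), np.log2(best_c.gamma)
    offsets = np.arange(-FINE_HALF_SPAN, FINE_HALF_SPAN + FINE_STEP / 2, FINE_STEP)
    fine = evaluate(_grid(ce0 + offsets, ge0 + offsets))

    best = max(coarse + fine, key=lambda r: (r[1], -r[0].C, -r[0].gamma))
    return GridSearchResult(
        coarse=[(p, a) for p, a, *_ in coarse],
        fine=[(p, a) for p, a, *_ in fine],
        selected=best[0],
        selected_cv_accuracy=best[1],
        selected_n_correct=best[2],
        n_total=best[3],
    )


def permutation_pvalue(
    eval_fn, labels, n_perm: int = 1000, seed: int = 0, add_one: bool = False
) -> tuple[float, float]:
    """Label-randomisation p-value for an accuracy computation.

    ``eval_fn(labels) -> accuracy %`` must be deterministic given a label
    vector.  The observed accuracy is computed once; labels are then
    permuted ``n_perm`` times and ``p = #{perm >= observed} / n_perm``
    (plain proportion, so p = 0 is attainable; ``add_one`` switches to the
    (b+1)/(n+1) estimator).  Returns (observed accuracy, p).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    observed = eval_fn(labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if eval_fn(rng.permutation(labels)) >= observed:
            exceed += 1
    if add_one:
        return observed, (exceed + 1) / (n_perm + 1)
    return observed, exceed / n_perm


def _seed_for(master_seed: int, *key: int) -> int:
    """Derive a 32-bit stream seed from a master seed and an index path."""
    return int(np.random.SeedSequence([int(master_seed), *map(int, key)]).generate_state(1)[0])


def within_task_repeat(
    epochs: Epochs,
    spec: FeatureSetSpec,
    repeat: int = 0,
    seed: int = 0,
    k: int = 10,
    n_perm: int = 1000,
    full_refit: bool = False,
    scale_jointly: bool = False,
) -> RepeatResult:
    """One within-task analysis: balance, grid search, CV, permutation test.

    With ``full_refit`` the grid search is re-run for every permutation
    (expensive); by default the hyperparameters stay fixed at the observed
    selection while the k-fold CV is re-run under permuted labels.
    """
    fm = balance_classes(extract_features(epochs, spec), seed)
    gs = nested_grid_search(fm, fm.labels, k=k, seed=seed, scale_jointly=scale_jointly)

    if full_refit:
        def eval_fn(labels):
            return nested_grid_search(
                fm, labels, k=k, seed=seed, scale_jointly=scale_jointly
            ).selected_cv_accuracy
    else:
        def eval_fn(labels):
            return cv_accuracy(fm, labels, gs.selected, k=k, seed=seed, scale_jointly=scale_jointly)

    rng_perm = np.random.default_rng(seed)
    observed = gs.selected_cv_accuracy
    exceed = 0
    for _ in range(n_perm):
        if eval_fn(rng_perm.permutation(fm.labels)) >= observed:
            exceed += 1
    p = exceed / n_perm
    return RepeatResult(
        repeat=repeat,
        accuracy=observed,
        p=p,
        n_correct=gs.selected_n_correct,
        n_total=gs.n_total,
        params=gs.selected,
    )


def transfer_classify(
    train_epochs: Epochs,
    test_epochs: Epochs,
    spec: FeatureSetSpec,
    seed: int = 0,
    repeat: int = 0,
    k: int = 10,
    n_perm: int = 1000,
) -> RepeatResult:
    """Train on one task, test on the balanced trials of the other.

    Hyperparameters come from the nested grid search on the (balanced,
    scaled) training task; the final SVM is fit on the full balanced
    training set and evaluated on the balanced test-task features scaled
    with the training scaler.  The permutation test permutes the test-set
    labels of the fixed model.
    """
    train_fm = balance_classes(extract_features(train_epochs, spec), seed)
    test_fm = balance_classes(extract_features(test_epochs, spec), _seed_for(seed, 1))

    gs = nested_grid_search(train_fm, train_fm.labels, k=k, seed=seed)
    scaler = fit_scaler(train_fm)
    clf = train_svm(apply_scaler(train_fm, scaler), gs.selected)
    predictions = clf.predict(apply_scaler(test_fm, scaler).values)

    def eval_fn(labels):
        return accuracy_rate(int(np.sum(predictions == _as_binary(labels))), len(labels))

    observed, p = permutation_pvalue(eval_fn, test_fm.labels, n_perm=n_perm, seed=_seed_for(seed, 2))
    n_correct = int(np.sum(predictions == _as_binary(test_fm.labels)))
    return RepeatResult(
        repeat=repeat,
        accuracy=observed,
        p=p,
        n_correct=n_correct,
        n_total=test_fm.n_trials,
        params=gs.selected,
    )


def repeat_and_aggregate(
    subject_epochs: dict[str, Epochs],
    spec: FeatureSetSpec,
    mode: str,
    n_repeats: int = 10,
    n_perm: int = 1000,
    master_seed: int = 0,
    k: int = 10,
    subject: int | None = None,
    scale_jointly: bool = False,
) -> ClassificationReport:
    """Repeat the analysis scheme with freshly drawn correct-trial samples.

    ``subject_epochs`` maps task name to that subject's epochs (one entry
    suffices for within-task modes).  Each repeat re-draws the balanced
    sample with a seed derived from ``master_seed``, runs the within-task
    CV or the across-task transfer plus its permutation test, and the
    repeats are aggregated as mean/min/max.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if subject is None:
        any_epochs = next(iter(subject_epochs.values()))
        subject = int(any_epochs.trial_meta["subject_id"].iloc[0])

    repeats = []
    for r in range(n_repeats):
        seed_r = _seed_for(master_seed, r)
        if mode.startswith("within-"):
            task = mode.removeprefix("within-")
            result = within_task_repeat(
                subject_epochs[task], spec, repeat=r, seed=seed_r, k=k, n_perm=n_perm,
                scale_jointly=scale_jointly,
            )
        else:
            train_task, test_task = mode.split("-to-")
            result = transfer_classify(
                subject_epochs[train_task],
                subject_epochs[test_task],
                spec,
                seed=seed_r,
                repeat=r,
                k=k,
                n_perm=n_perm,
            )
        repeats.append(result)
    return ClassificationReport(subject=subject, feature_set=spec.name, mode=mode, repeats=repeats)
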