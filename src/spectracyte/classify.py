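"""Gradient-boosted classification of single-cell spectra.

Implements the full training protocol used for CAR-vs-Mock and cell-type
discrimination: Savitzky-Golay derivative augmentation, an 80:20
class-stratified train/test split, hyperparameter search under 5-fold
stratified CV with early stopping (validation AUC for binary problems,
log loss for multiclass), a 10-fold stratified final CV on the training
split for accuracy/confusion reporting, held-out ROC/AUC, per-donor
training with bootstrap-averaged common-grid ROC curves, and gain-based
feature-importance profiles computed on non-derivative-augmented spectra.

The boosting backend is LightGBM through its sklearn API; the protocol is
the contribution here, and any gradient-boosted tree library exposing
fit / predict-probability / per-feature gain would satisfy it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lightgbm import LGBMClassifier, early_stopping, log_evaluation
from scipy.signal import savgol_filter
from sklearn.metrics import confusion_matrix, log_loss, roc_auc_score, roc_curve
from sklearn.model_selection import ParameterSampler, StratifiedKFold, train_test_split

from .spectra import SpectraSet, WavenumberAxis

__all__ = [
    "FeatureMatrix",
    "TrainProtocol",
    "ClassifierReport",
    "PooledDonorSummary",
    "ImportanceProfile",
    "augment_derivatives",
    "plain_features",
    "train_classifier",
    "multiclass_train",
    "per_donor_protocol",
    "importance_profile",
]


@dataclass
class FeatureMatrix:
    """Feature rows per spectrum: ``[x, x', x'']`` blocks when augmented."""

    X: np.ndarray
    y: np.ndarray  # class labels (strings)
    donors: np.ndarray
    ids: list[str]
    augmented: bool
    axis: WavenumberAxis

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        idx = np.flatnonzero(mask)
        return FeatureMatrix(
            X=self.X[idx],
            y=self.y[idx],
            donors=self.donors[idx],
            ids=[self.ids[i] for i in idx],
            augmented=self.augmented,
            axis=self.axis,
        )


def augment_derivatives(
    sset: SpectraSet, window: int = 11, polyorder: int = 3
) -> FeatureMatrix:
    """Append first/second Savitzky-Golay derivative blocks to the spectra.

    Edge channels are handled by a polynomial fit within the one-sided
    window (``mode='interp'``), so the derivative of a constant spectrum is
    exactly zero everywhere.
    """
    p = sset.axis.n_channels
    if window > p:
        raise ValueError(f"window {window} exceeds {p} channels")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    X = sset.intensity_matrix()
    d1 = savgol_filter(X, window, polyorder, deriv=1, axis=1, mode="interp")
    d2 = savgol_filter(X, window, polyorder, deriv=2, axis=1, mode="interp")
    return FeatureMatrix(
        X=np.hstack([X, d1, d2]),
        y=sset.labels(),
        donors=sset.donors(),
        ids=sset.ids(),
        augmented=True,
        axis=sset.axis,
    )


def plain_features(sset: SpectraSet) -> FeatureMatrix:
    """Non-derivative-augmented features (used for importance analysis)."""
    return FeatureMatrix(
        X=sset.intensity_matrix(),
        y=sset.labels(),
        donors=sset.donors(),
        ids=sset.ids(),
        augmented=False,
        axis=sset.axis,
    )


@dataclass(frozen=True)
class TrainProtocol:
    """Split / tuning / CV protocol constants.

    The hyperparameter search space is fixed and documented in
    ``SEARCH_SPACE``; the search backend is a seeded random sampler with an
    evaluation budget of ``n_trials`` (0 skips the search and keeps LightGBM
    defaults; tree count is still selected from training-split learning
    curves).
    """

    test_fraction: float = 0.2
    tuning_folds: int = 5
    final_cv_folds: int = 10
    early_stopping_rounds: int = 150
    max_boosting_rounds: int = 2000
    n_trials: int = 50
    min_class_size: int = 20
    seed: int = 0

    @property
    def rng_seed(self) -> int:
        return int(self.seed) % (2**31 - 1)


SEARCH_SPACE = {
    "learning_rate": np.geomspace(0.01, 0.3, 20),
    "num_leaves": [15, 31, 63, 127],
    "max_depth": [-1, 4, 6, 8],
    "min_child_samples": [5, 10, 20, 50],
    "subsample": np.linspace(0.6, 1.0, 9),
    "subsample_freq": [1],
    "colsample_bytree": np.linspace(0.5, 1.0, 11),
    "reg_alpha": np.geomspace(1e-8, 10.0, 20),
    "reg_lambda": np.geomspace(1e-8, 10.0, 20),
}


@dataclass
class ClassifierReport:
    classes: list[str]
    fold_confusions: list[np.ndarray]  # row-normalized, one per final-CV fold
    confusion: np.ndarray  # row-normalized aggregate over folds
    cv_accuracy: float
    roc_fpr: np.ndarray | None
    roc_tpr: np.ndarray | None
    auc: float
    best_params: dict
    n_estimators: int
    augmented: bool
    model: LGBMClassifier


def _base_params(protocol: TrainProtocol, n_classes: int, scale_pos_weight: float | None) -> dict:
    params: dict = dict(
        random_state=protocol.rng_seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbosity=-1,
    )
    if n_classes == 2:
        params["objective"] = "binary"
        if scale_pos_weight is not None:
            params["scale_pos_weight"] = scale_pos_weight
    else:
        params["objective"] = "multiclass"
        params["num_class"] = n_classes
        params["class_weight"] = "balanced"
    return params


def _cv_early_stop_score(
    X: np.ndarray,
    y: np.ndarray,
    params: dict,
    protocol: TrainProtocol,
    multiclass: bool,
) -> tuple[float, int]:
    """Mean validation score and mean best iteration over the tuning folds.

    Score is AUC (higher better) for binary, negative log loss for
    multiclass, so 'higher is better' holds for both.
    """
    skf = StratifiedKFold(
        n_splits=protocol.tuning_folds, shuffle=True, random_state=protocol.rng_seed
    )
    metric = "multi_logloss" if multiclass else "auc"
    scores, iters = [], []
    for tr, va in skf.split(X, y):
        model = LGBMClassifier(n_estimators=protocol.max_boosting_rounds, **params)
        model.fit(
            X[tr],
            y[tr],
            eval_set=[(X[va], y[va])],
            eval_metric=metric,
            callbacks=[
                early_stopping(protocol.early_stopping_rounds, verbose=False),
                log_evaluation(0),
            ],
        )
        proba = model.predict_proba(X[va])
        if multiclass:
            scores.append(-log_loss(y[va], proba, labels=np.unique(y)))
        else:
            scores.append(roc_auc_score(y[va], proba[:, 1]))
        iters.append(model.best_iteration_ or protocol.max_boosting_rounds)
    return float(np.mean(scores)), int(round(np.mean(iters)))


def _train(features: FeatureMatrix, protocol: TrainProtocol, multiclass: bool) -> ClassifierReport:
    X, y = features.X, features.y
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training requires at least 2 classes")
    if multiclass and classes.size < 3:
        raise ValueError("multiclass training requires at least 3 classes")
    if counts.min() < protocol.min_class_size:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} spectra "
            f"(< {protocol.min_class_size})"
        )
    if counts.min() < protocol.final_cv_folds:
        raise ValueError("smallest class has fewer members than CV folds")

    y_enc = np.searchsorted(classes, y)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y_enc,
        test_size=protocol.test_fraction,
        stratify=y_enc,
        random_state=protocol.rng_seed,
    )

    spw = None
    if classes.size == 2:
        spw = float((y_tr == 0).sum()) / max(float((y_tr == 1).sum()), 1.0)
    base = _base_params(protocol, classes.size, spw)

    # hyperparameter search + learning-curve tree-count selection, on the
    # training split only
    best_params: dict = {}
    if protocol.n_trials > 0:
        sampler = ParameterSampler(
            SEARCH_SPACE, n_iter=protocol.n_trials, random_state=protocol.rng_seed
        )
        best_score = -np.inf
        best_iters = protocol.max_boosting_rounds
        for cand in sampler:
            cand = {k: (float(v) if isinstance(v, np.floating) else v) for k, v in cand.items()}
            score, iters = _cv_early_stop_score(X_tr, y_tr, {**base, **cand}, protocol, multiclass)
            if score > best_score:
                best_score, best_params, best_iters = score, cand, iters
        n_estimators = best_iters
    else:
        _, n_estimators = _cv_early_stop_score(X_tr, y_tr, base, protocol, multiclass)

    final_params = {**base, **best_params}

    # final 10-fold stratified CV on the training split
    skf = StratifiedKFold(
        n_splits=protocol.final_cv_folds, shuffle=True, random_state=protocol.rng_seed
    )
    fold_confusions = []
    agg = np.zeros((classes.size, classes.size))
    correct = total = 0
    for tr, va in skf.split(X_tr, y_tr):
        m = LGBMClassifier(n_estimators=n_estimators, **final_params)
        m.fit(X_tr[tr], y_tr[tr])
        pred = m.predict(X_tr[va])
        cm = confusion_matrix(y_tr[va], pred, labels=np.arange(classes.size)).astype(float)
        agg += cm
        correct += int((pred == y_tr[va]).sum())
        total += va.size
        with np.errstate(invalid="ignore", divide="ignore"):
            fold_confusions.append(cm / cm.sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        confusion = agg / agg.sum(axis=1, keepdims=True)
    cv_accuracy = correct / total

    # held-out evaluation
    model = LGBMClassifier(n_estimators=n_estimators, **final_params)
    model.fit(X_tr, y_tr)
    proba = model.predict_proba(X_te)
    if classes.size == 2:
        fpr, tpr, _ = roc_curve(y_te, proba[:, 1])
        auc = float(roc_auc_score(y_te, proba[:, 1]))
    else:
        fpr = tpr = None
        auc = float(
            roc_auc_score(y_te, proba, multi_class="ovr", labels=np.arange(classes.size))
        )

    return ClassifierReport(
        classes=list(classes),
        fold_confusions=fold_confusions,
        confusion=confusion,
        cv_accuracy=float(cv_accuracy),
        roc_fpr=fpr,
        roc_tpr=tpr,
        auc=auc,
        best_params=best_params,
        n_estimators=int(n_estimators),
        augmented=features.augmented,
        model=model,
    )


def train_classifier(features: FeatureMatrix, protocol: TrainProtocol = TrainProtocol()) -> ClassifierReport:
    """Binary (or generic) training under the full protocol; see module docs."""
    classes = np.unique(features.y)
    return _train(features, protocol, multiclass=classes.size > 2)


def multiclass_train(features: FeatureMatrix, protocol: TrainProtocol = TrainProtocol()) -> ClassifierReport:
    """Multiclass variant: identical protocol with validation log loss as the
    tuning criterion (>= 3 classes required)."""
    return _train(features, protocol, multiclass=True)


@dataclass
class PooledDonorSummary:
    donor_accuracies: dict[str, float]
    mean_accuracy: float
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray | None
    tpr_low: np.ndarray | None
    tpr_high: np.ndarray | None
    skipped_donors: list[str] = field(default_factory=list)


ROC_GRID_POINTS = 101
ROC_BOOTSTRAP = 1000


def per_donor_protocol(
    sset: SpectraSet,
    protocol: TrainProtocol = TrainProtocol(),
    augment: bool = True,
    window: int = 11,
    polyorder: int = 3,
) -> tuple[dict[str, ClassifierReport], PooledDonorSummary]:
    """One model per donor, plus a pooled summary with the bootstrap-averaged
    common-grid ROC (101 FPR points, 1000 donor resamples, 95% CI)."""
    donors = sorted(set(sset.donors()))
    if len(donors) < 1:
        raise ValueError("no donors in set")
    reports: dict[str, ClassifierReport] = {}
    skipped: list[str] = []
    for d in donors:
        sub = sset.select(sset.donors() == d, note=f"donor {d}")
        feats = augment_derivatives(sub, window, polyorder) if augment else plain_features(sub)
        try:
            reports[d] = train_classifier(feats, protocol)
        except ValueError as exc:
            warnings.warn(f"donor {d!r} skipped: {exc}")
            skipped.append(d)
    if not reports:
        raise ValueError("no donor satisfied the training preconditions")

    accs = {d: r.cv_accuracy for d, r in reports.items()}
    grid = np.linspace(0.0, 1.0, ROC_GRID_POINTS)
    curves = [
        np.interp(grid, r.roc_fpr, r.roc_tpr)
        for r in reports.values()
        if r.roc_fpr is not None
    ]
    mean_tpr = tpr_low = tpr_high = None
    if curves:
        arr = np.vstack(curves)
        rng = np.random.default_rng(protocol.rng_seed)
        boots = np.empty((ROC_BOOTSTRAP, grid.size))
        for b in range(ROC_BOOTSTRAP):
            pick = rng.integers(0, arr.shape[0], size=arr.shape[0])
            boots[b] = arr[pick].mean(axis=0)
        mean_tpr = boots.mean(axis=0)
        tpr_low = np.percentile(boots, 2.5, axis=0)
        tpr_high = np.percentile(boots, 97.5, axis=0)
    summary = PooledDonorSummary(
        donor_accuracies=accs,
        mean_accuracy=float(np.mean(list(accs.values()))),
        fpr_grid=grid,
        mean_tpr=mean_tpr,
        tpr_low=tpr_low,
        tpr_high=tpr_high,
        skipped_donors=skipped,
    )
    return reports, summary


@dataclass
class ImportanceProfile:
    wavenumbers: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    per_donor: np.ndarray  # (n_donors, p)


def importance_profile(
    per_donor_reports: dict[str, ClassifierReport] | list[ClassifierReport],
    axis: WavenumberAxis,
) -> ImportanceProfile:
    """Across-donor gain-importance profile on the wavenumber axis.

    Per donor: gain per wavenumber -> sum-normalize -> min-max scale to
    [0, 1]; the profile reports the across-donor mean and SD.  Models must
    have been trained on non-derivative-augmented features so that each
    feature is one wavenumber.
    """
    reports = list(per_donor_reports.values()) if isinstance(per_donor_reports, dict) else list(per_donor_reports)
    if not reports:
        raise ValueError("no reports given")
    p = axis.n_channels
    rows = []
    for r in reports:
        if r.augmented:
            raise ValueError(
                "importance_profile requires models trained on "
                "non-derivative-augmented features"
            )
        gain = np.asarray(r.model.booster_.feature_importance(importance_type="gain"), dtype=float)
        if gain.size != p:
            raise ValueError(f"model has {gain.size} features, axis has {p} channels")
        total = gain.sum()
        if total > 0:
            gain = gain / total
        lo, hi = gain.min(), gain.max()
        rows.append((gain - lo) / (hi - lo) if hi > lo else np.zeros(p))
    arr = np.vstack(rows)
    return ImportanceProfile(
        wavenumbers=axis.values.copy(),
        mean=arr.mean(axis=0),
        sd=arr.std(axis=0),
        per_donor=arr,
    )
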