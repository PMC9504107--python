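"""Windowing, the 23-feature extractor, and multi-classifier evaluation.

Joint-angle time series are cut into 1000 ms windows with 50% overlap.  From
each window and channel, 23 features are extracted:

* 12 time-domain: mean, median, std, median absolute deviation, 25th and 75th
  percentiles, interquartile range, skewness, kurtosis (excess), variance,
  Shannon entropy of a 16-bin amplitude histogram (natural log), and spectral
  entropy of the normalized one-sided power spectrum.
* 6 frequency/autoregressive scalars: frequency and value of the spectral
  maximum, the maximum's share of total power, and the main-peak value plus
  second-peak height and frequency of an order-4 Yule-Walker autoregressive
  power spectrum.
* 5 spectral-power bands: total power in five equal-width bands spanning
  0-10 Hz (the body-motion band).

Constant (zero-variance) windows use degenerate rules — skewness, kurtosis
and both entropies are 0, the AR spectrum is flat — so no feature is ever NaN.

Evaluation follows a held-out protocol: a stratified test split is carved
first, 10-fold cross-validation on the remainder selects the best candidate
per classifier family, and the selected model is scored on the untouched test
split (weighted precision/recall/F1, micro-averaged one-vs-rest ROC-AUC and
AUPRC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.linalg import solve_toeplitz
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler, label_binarize
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from posturekit.errors import EmptyClass, InsufficientSamplesPerClass, TooShort
from posturekit.skeleton import ANGLE_CHANNELS, JointAngleSeries

__all__ = [
    "FEATURE_NAMES",
    "TASK_LABELS",
    "FeatureWindow",
    "EvaluationReport",
    "segment_windows",
    "extract_features",
    "build_dataset",
    "evaluate_classifiers",
]

FEATURE_NAMES = [
    "mean", "med", "std", "mad", "quantile1", "quantile2", "iqr",
    "skewness", "kurtosis", "var", "entropy", "spectral_entropy",
    "maxfreq", "maxval", "maxratio", "ar_peak", "ar_height", "ar_position",
    "spwf1", "spwf2", "spwf3", "spwf4", "spwf5",
]

TASK_LABELS = {1: "recite", 2: "reading_comprehension", 3: "browse", 4: "music"}

ENTROPY_BINS = 16
AR_ORDER = 4
AR_GRID = 256
POWER_BAND_TOP_HZ = 10.0
N_BANDS = 5


def segment_windows(series, window_ms: float = 1000.0, overlap: float = 0.5,
                    rate: Optional[float] = None) -> List[np.ndarray]:
    """Cut a series into fixed windows of ``window_ms`` with fractional overlap.

    Stride is ``window * (1 - overlap)``; a trailing partial window is dropped,
    giving ``floor((N - w) / stride) + 1`` windows.

    Accepts a JointAngleSeries (windows are (w, n_channels) matrices) or a 1-D
    array with an explicit ``rate``.

    Raises TooShort when the series is shorter than one window.
    """
    if isinstance(series, JointAngleSeries):
        data = series.as_matrix()
        rate = series.rate
    else:
        data = np.asarray(series, dtype=float)
        if rate is None:
            raise ValueError("rate required for plain-array input")
    w = int(round(window_ms / 1000.0 * rate))
    if w < 1:
        raise ValueError("window shorter than one sample")
    stride = max(1, int(round(w * (1.0 - overlap))))
    n = len(data)
    if n < w:
        raise TooShort(f"series of {n} samples shorter than one {w}-sample window")
    return [data[i:i + w] for i in range(0, n - w + 1, stride)]


# ---------------------------------------------------------------------------
# 23-feature extractor

def _histogram_entropy(x: np.ndarray) -> float:
    counts, _ = np.histogram(x, bins=ENTROPY_BINS)
    p = counts[counts > 0] / len(x)
    return float(-np.sum(p * np.log(p)))


def _one_sided_power(x: np.ndarray, rate: float):
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / rate)
    return freqs[1:], spec[1:]  # DC excluded: offsets carry no motion content


def _yule_walker_ar(x: np.ndarray, order: int = AR_ORDER):
    """AR coefficients and innovation variance via Yule-Walker equations
    (autocovariances with the (n-k)-denominator 'adjusted' normalization)."""
    x = x - x.mean()
    n = len(x)
    r = np.array([np.dot(x[:n - k], x[k:]) / (n - k) for k in range(order + 1)])
    if r[0] <= 0:
        return np.zeros(order), 0.0
    rho = solve_toeplitz(r[:-1], r[1:])
    sigma2 = r[0] - np.dot(rho, r[1:])
    return rho, max(float(sigma2), 0.0)


def _ar_spectrum(x: np.ndarray, rate: float):
    """Order-4 autoregressive power spectrum on a uniform grid up to Nyquist."""
    rho, sigma2 = _yule_walker_ar(x)
    freqs = np.linspace(0.0, rate / 2.0, AR_GRID)
    if sigma2 == 0.0:
        return freqs, np.zeros(AR_GRID)
    k = np.arange(1, AR_ORDER + 1)
    denom = np.abs(1.0 - np.exp(-2j * np.pi * np.outer(freqs / rate, k)) @ rho) ** 2
    return freqs, sigma2 / np.maximum(denom, 1e-300)


def _spectrum_peaks(freqs: np.ndarray, power: np.ndarray):
    """(main peak value, second-peak height, second-peak frequency) of a
    spectrum; local maxima ranked by height, endpoints eligible."""
    if len(power) == 0 or np.all(power == 0):
        return 0.0, 0.0, 0.0
    interior = np.where((power[1:-1] >= power[:-2]) & (power[1:-1] >= power[2:]))[0] + 1
    cand = list(interior)
    if len(power) >= 2:
        if power[0] >= power[1]:
            cand.append(0)
        if power[-1] >= power[-2]:
            cand.append(len(power) - 1)
    cand = sorted(set(cand), key=lambda i: -power[i])
    main = float(power[cand[0]]) if cand else float(power.max())
    if len(cand) > 1:
        return main, float(power[cand[1]]), float(freqs[cand[1]])
    return main, 0.0, 0.0


def extract_features(window: np.ndarray, rate: float) -> np.ndarray:
    """The 23-feature vector of a single-channel window (ordered as
    FEATURE_NAMES)."""
    x = np.asarray(window, dtype=float).ravel()
    if len(x) == 0:
        raise ValueError("empty window")
    n = len(x)

    mean = float(x.mean())
    med = float(np.median(x))
    var = float(x.var())
    std = float(np.sqrt(var))
    mad = float(np.median(np.abs(x - med)))
    q1 = float(np.percentile(x, 25))
    q3 = float(np.percentile(x, 75))
    iqr = q3 - q1
    if std > 0:
        z = (x - mean) / std
        skewness = float(np.mean(z**3))
        kurtosis = float(np.mean(z**4) - 3.0)
        entropy = _histogram_entropy(x)
    else:
        skewness = kurtosis = entropy = 0.0

    freqs, power = _one_sided_power(x, rate)
    total = float(power.sum())
    # a constant window leaves only FFT round-off in the non-DC bins
    if std == 0.0:
        total = 0.0
    if total > 0:
        p = power / total
        pn = p[p > 0]
        spectral_entropy = float(-np.sum(pn * np.log(pn)))
        imax = int(np.argmax(power))
        maxfreq = float(freqs[imax])
        maxval = float(power[imax])
        maxratio = maxval / total
        edges = np.linspace(0.0, POWER_BAND_TOP_HZ, N_BANDS + 1)
        bands = [float(power[(freqs > lo) & (freqs <= hi)].sum())
                 for lo, hi in zip(edges[:-1], edges[1:])]
    else:
        spectral_entropy = maxfreq = maxval = maxratio = 0.0
        bands = [0.0] * N_BANDS

    ar_freqs, ar_power = _ar_spectrum(x, rate)
    ar_peak, ar_height, ar_position = _spectrum_peaks(ar_freqs, ar_power)

    return np.array([
        mean, med, std, mad, q1, q3, iqr, skewness, kurtosis, var,
        entropy, spectral_entropy,
        maxfreq, maxval, maxratio, ar_peak, ar_height, ar_position,
        *bands,
    ])


@dataclass(frozen=True)
class FeatureWindow:
    """One labeled window: per-channel 23-feature blocks concatenated."""

    index: int
    label: int
    features: np.ndarray
    channels: Sequence[str] = tuple(ANGLE_CHANNELS)

    def __post_init__(self):
        if self.label not in TASK_LABELS:
            raise ValueError(f"label {self.label} outside {sorted(TASK_LABELS)}")
        object.__setattr__(self, "features", np.asarray(self.features, dtype=float))
        if np.any(~np.isfinite(self.features)):
            raise ValueError("non-finite feature value")


def feature_columns(channels: Sequence[str]) -> List[str]:
    return [f"{ch}_{f}" for ch in channels for f in FEATURE_NAMES]


def build_dataset(angle_series: Dict[int, List[JointAngleSeries]],
                  window_ms: float = 1000.0,
                  overlap: float = 0.5) -> List[FeatureWindow]:
    """Window and featurize labeled joint-angle series into a flat dataset.

    ``angle_series`` maps task label (1=recite, 2=reading comprehension,
    3=browse, 4=music) to that task's recordings.  Each window contributes one
    row: the 23-feature blocks of every angle channel, concatenated.

    Raises EmptyClass if a label yields no windows.
    """
    rows: List[FeatureWindow] = []
    idx = 0
    for label in sorted(angle_series):
        if label not in TASK_LABELS:
            raise ValueError(f"label {label} outside {sorted(TASK_LABELS)}")
        count_before = len(rows)
        for series in angle_series[label]:
            for win in segment_windows(series, window_ms, overlap):
                feats = np.concatenate([extract_features(win[:, j], series.rate)
                                        for j in range(win.shape[1])])
                rows.append(FeatureWindow(idx, label, feats))
                idx += 1
        if len(rows) == count_before:
            raise EmptyClass(f"task {label} ({TASK_LABELS[label]}) produced no windows")
    return rows


# ---------------------------------------------------------------------------
# Classifier evaluation

@dataclass
class EvaluationReport:
    """Test-split metrics and per-fold validation accuracies per classifier."""

    metrics: Dict[str, Dict[str, float]] = field(default_factory=dict)
    fold_scores: Dict[str, List[float]] = field(default_factory=dict)
    chosen_params: Dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "fold_scores": self.fold_scores,
            "chosen_params": {k: {p: repr(v) for p, v in d.items()}
                              for k, d in self.chosen_params.items()},
        }


def _classifier_families(seed: int):
    """Candidate grids per family; CV accuracy picks the winner."""
    return {
        "logistic_regression": [
            {"C": c} for c in (0.1, 1.0, 10.0)
        ],
        "decision_tree": [
            {"max_depth": d} for d in (None, 10)
        ],
        "svm": [
            {"C": c} for c in (1.0, 10.0)
        ],
        "random_forest": [
            {"n_estimators": 100}
        ],
        "knn": [
            {"n_neighbors": k} for k in (3, 5)
        ],
    }


def _make_estimator(family: str, params: dict, seed: int):
    if family == "logistic_regression":
        clf = LogisticRegression(max_iter=2000, random_state=seed, **params)
    elif family == "decision_tree":
        clf = DecisionTreeClassifier(random_state=seed, **params)
    elif family == "svm":
        clf = SVC(kernel="rbf", random_state=seed, **params)
    elif family == "random_forest":
        clf = RandomForestClassifier(random_state=seed, **params)
    elif family == "knn":
        clf = KNeighborsClassifier(**params)
    else:  # pragma: no cover
        raise ValueError(family)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def evaluate_classifiers(dataset: List[FeatureWindow],
                         k: int = 10,
                         test_fraction: float = 0.2,
                         seed: int = 0) -> EvaluationReport:
    """Hold out a stratified test split, select per-family models by k-fold CV
    accuracy on the remainder, and report test metrics.

    Metrics per family: accuracy, weighted precision/recall/F1, micro-averaged
    one-vs-rest ROC-AUC and AUPRC.

    Raises InsufficientSamplesPerClass when any class has too few windows for
    the stratified split and k folds.
    """
    X = np.array([fw.features for fw in dataset])
    y = np.array([fw.label for fw in dataset])
    classes, counts = np.unique(y, return_counts=True)
    min_needed = max(int(np.ceil(1.0 / test_fraction)), k + 1)
    if counts.min() < min_needed:
        raise InsufficientSamplesPerClass(
            f"smallest class has {counts.min()} windows; "
            f"need >= {min_needed} for a {test_fraction:.0%} test split and {k}-fold CV")

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_te_bin = label_binarize(y_te, classes=classes)

    report = EvaluationReport()
    for family, grid in _classifier_families(seed).items():
        best_params, best_score, best_folds = None, -np.inf, None
        for params in grid:
            est = _make_estimator(family, params, seed)
            folds = cross_val_score(est, X_tr, y_tr, cv=cv, scoring="accuracy")
            if folds.mean() > best_score:
                best_params, best_score, best_folds = params, folds.mean(), folds
        est = _make_estimator(family, best_params, seed)
        est.fit(X_tr, y_tr)
        y_pred = est.predict(X_te)
        if hasattr(est[-1], "predict_proba"):
            proba = est.predict_proba(X_te)
        else:  # margin scores rank identically for ROC/PR purposes
            proba = est.decision_function(X_te)
        report.metrics[family] = {
            "accuracy": float(accuracy_score(y_te, y_pred)),
            "precision": float(precision_score(y_te, y_pred, average="weighted",
                                               zero_division=0)),
            "recall": float(recall_score(y_te, y_pred, average="weighted",
                                         zero_division=0)),
            "f1": float(f1_score(y_te, y_pred, average="weighted", zero_division=0)),
            "auc": float(roc_auc_score(y_te_bin, proba, average="micro")),
            "auprc": float(average_precision_score(y_te_bin, proba, average="micro")),
        }
        report.fold_scores[family] = [float(s) for s in best_folds]
        report.chosen_params[family] = dict(best_params)
    return report
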