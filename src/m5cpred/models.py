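"""Classifier training, scoring, stringency calibration and persistence.

The production predictor is a random forest over one-hot window features
(300 trees at the optimum, selected together with the 1:30 training ratio
by cross-validation). Three baselines — logistic regression, Gaussian
naive Bayes and a single pruned decision tree — share the same interface
so encoding schemes and learners can be compared on identical folds.

Scores are positive-class probabilities in [0, 1] (never hard votes):
continuous scores are what make FPR-calibrated stringency thresholds
possible. Three stringency levels are published with each model:

====== ==========================
level  nominal false-positive rate
high   1%
medium 5%
low    10%
====== ==========================

Calibration uses an order-statistic rule on a held-out negative sample
drawn from training-side transcripts (never test-side, to keep evaluation
honest): the threshold for level α is the smallest observed score t such
that the fraction of calibration negatives scoring strictly above t is
≤ α — the ⌈(1−α)·n⌉-th order statistic of the negative scores.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from . import __version__
from .datasets import LabelledDataset
from .encode import SCHEMES, encode_batch
from .errors import (
    BundleError,
    BundleVersionError,
    EmptyNegativesError,
    M5cError,
    ShapeMismatchError,
    SingleClassError,
)
from .seqio import SequenceWindow

ALGORITHMS = ("random_forest", "logistic_regression", "naive_bayes",
              "decision_tree")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "random_forest": {"n_tree": 300},
    "logistic_regression": {"max_iter": 1000},
    "naive_bayes": {},
    # minsplit/cp/maxdepth as used for the rpart-style baseline; cp maps to
    # sklearn's cost-complexity pruning alpha, the nearest available control.
    "decision_tree": {"min_split": 35, "complexity": 0.00001, "max_depth": 30},
}

STRINGENCY_FPR = {"high": 0.01, "medium": 0.05, "low": 0.10}

BUNDLE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ThresholdSet:
    """Score cutoffs for the three stringency levels (monotone: high ≥
    medium ≥ low, since a stricter FPR demands a higher score)."""

    levels: Mapping[str, float]
    calibration_size: int

    def __post_init__(self) -> None:
        vals = [self.levels[k] for k in ("high", "medium", "low")
                if k in self.levels]
        if any(a < b for a, b in zip(vals, vals[1:])):
            raise M5cError("thresholds must be non-increasing from high to low")

    def call(self, score: float, level: str) -> bool:
        return score > self.levels[level]


@dataclass
class TrainedPredictor:
    """A fitted learner plus everything needed to reproduce its scores."""

    algorithm: str
    hyperparameters: dict
    encoding_scheme: str
    w: int
    tissue: str
    seed: int
    model: object  # fitted scikit-learn estimator
    thresholds: ThresholdSet | None = None
    version: str = field(default=__version__)


def _build_estimator(algorithm: str, hyperparameters: dict, seed: int):
    if algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(hyperparameters.get("n_tree", 300)),
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "logistic_regression":
        return LogisticRegression(
            max_iter=int(hyperparameters.get("max_iter", 1000)),
        )
    if algorithm == "naive_bayes":
        return GaussianNB()
    if algorithm == "decision_tree":
        return DecisionTreeClassifier(
            min_samples_split=int(hyperparameters.get("min_split", 35)),
            ccp_alpha=float(hyperparameters.get("complexity", 0.00001)),
            max_depth=int(hyperparameters.get("max_depth", 30)),
            random_state=seed,
        )
    raise M5cError(f"unknown algorithm {algorithm!r}; expected one of "
                   f"{ALGORITHMS}")


def train(dataset: LabelledDataset,
          algorithm: str = "random_forest",
          hyperparameters: Mapping | None = None,
          encoding_scheme: str = "one_hot",
          seed: int = 0) -> TrainedPredictor:
    """Fit a predictor on a training dataset.

    The score contract: ``predict_scores`` returns the estimated positive
    class probability, reproducible under a fixed seed.
    """
    if encoding_scheme not in SCHEMES:
        raise M5cError(f"unknown encoding scheme {encoding_scheme!r}")
    if algorithm not in ALGORITHMS:
        raise M5cError(f"unknown algorithm {algorithm!r}; expected one of "
                       f"{ALGORITHMS}")
    if dataset.role != "train":
        warnings.warn(f"training on a dataset with role={dataset.role!r}",
                      stacklevel=2)
    labels = np.asarray(dataset.labels)
    if len(set(labels.tolist())) < 2:
        raise SingleClassError("training requires both classes")
    params = dict(DEFAULT_HYPERPARAMETERS[algorithm])
    if hyperparameters:
        params.update(hyperparameters)
    matrix = encode_batch(dataset.windows, scheme=encoding_scheme)
    estimator = _build_estimator(algorithm, params, seed)
    estimator.fit(matrix.values, labels)
    return TrainedPredictor(
        algorithm=algorithm,
        hyperparameters=params,
        encoding_scheme=encoding_scheme,
        w=matrix.w,
        tissue=dataset.tissue,
        seed=seed,
        model=estimator,
    )


def predict_scores(predictor: TrainedPredictor,
                   windows: Sequence[SequenceWindow]) -> np.ndarray:
    """Positive-class probability for each window, input order preserved."""
    windows = list(windows)
    if not windows:
        return np.empty(0)
    if any(win.w != predictor.w for win in windows):
        raise ShapeMismatchError(
            f"window width does not match the predictor's w={predictor.w}"
        )
    matrix = encode_batch(windows, scheme=predictor.encoding_scheme)
    proba = predictor.model.predict_proba(matrix.values)
    positive_col = list(predictor.model.classes_).index(1)
    return proba[:, positive_col]


def calibrate_thresholds(predictor: TrainedPredictor,
                         calibration_negatives: Sequence[SequenceWindow],
                         fpr_levels: Mapping[str, float] | None = None,
                         ) -> ThresholdSet:
    """Order-statistic calibration of the stringency cutoffs.

    For each level α the threshold is the ⌈(1−α)·n⌉-th smallest negative
    score — the smallest observed t with ``frac(score > t) ≤ α`` on the
    calibration sample. The resulting set is attached to the predictor.
    """
    levels = dict(STRINGENCY_FPR if fpr_levels is None else fpr_levels)
    negatives = list(calibration_negatives)
    if not negatives:
        raise EmptyNegativesError("calibration requires negative windows")
    n = len(negatives)
    min_alpha = min(levels.values())
    if n < 1.0 / min_alpha:
        warnings.warn(
            f"{n} calibration negatives cannot resolve an FPR of "
            f"{min_alpha:.2%}; thresholds will be coarse",
            stacklevel=2,
        )
    scores = np.sort(predict_scores(predictor, negatives))
    thresholds = {}
    for name, alpha in levels.items():
        k = int(np.ceil((1.0 - alpha) * n))
        k = min(max(k, 1), n)
        thresholds[name] = float(scores[k - 1])
    result = ThresholdSet(levels=thresholds, calibration_size=n)
    predictor.thresholds = result
    return result


# ---------------------------------------------------------------------------
# persistence: directory bundle with manifest.json + serialized learner
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def save_predictor(predictor: TrainedPredictor, path: str | Path) -> Path:
    """Write a model bundle: ``manifest.json`` (human-readable) plus the
    joblib-serialized learner, checksummed so tampering is detected."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    model_file = out / "model.joblib"
    joblib.dump(predictor.model, model_file)
    manifest = {
        "bundle_format": BUNDLE_FORMAT_VERSION,
        "tool_version": predictor.version,
        "algorithm": predictor.algorithm,
        "hyperparameters": predictor.hyperparameters,
        "encoding_scheme": predictor.encoding_scheme,
        "w": predictor.w,
        "tissue": predictor.tissue,
        "seed": predictor.seed,
        "thresholds": (
            None if predictor.thresholds is None else {
                "levels": dict(predictor.thresholds.levels),
                "calibration_size": predictor.thresholds.calibration_size,
            }
        ),
        "model_sha256": _sha256(model_file),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def load_predictor(path: str | Path) -> TrainedPredictor:
    """Load a bundle; corrupt or version-incompatible bundles fail loudly
    rather than silently mispredicting."""
    bundle = Path(path)
    manifest_file = bundle / "manifest.json"
    model_file = bundle / "model.joblib"
    if not manifest_file.exists() or not model_file.exists():
        raise BundleError(f"{bundle}: not a model bundle "
                          "(manifest.json/model.joblib missing)")
    try:
        manifest = json.loads(manifest_file.read_text())
    except json.JSONDecodeError as exc:
        raise BundleError(f"{bundle}: unreadable manifest: {exc}") from exc
    if manifest.get("bundle_format") != BUNDLE_FORMAT_VERSION:
        raise BundleVersionError(
            f"{bundle}: bundle format {manifest.get('bundle_format')!r} is "
            f"incompatible with this version (expects "
            f"{BUNDLE_FORMAT_VERSION})"
        )
    checksum = _sha256(model_file)
    if checksum != manifest.get("model_sha256"):
        raise BundleError(
            f"{bundle}: model checksum mismatch — bundle corrupt or tampered"
        )
    model = joblib.load(model_file)
    thresholds = None
    if manifest.get("thresholds"):
        thresholds = ThresholdSet(
            levels=manifest["thresholds"]["levels"],
            calibration_size=manifest["thresholds"]["calibration_size"],
        )
    return TrainedPredictor(
        algorithm=manifest["algorithm"],
        hyperparameters=manifest["hyperparameters"],
        encoding_scheme=manifest["encoding_scheme"],
        w=int(manifest["w"]),
        tissue=manifest["tissue"],
        seed=int(manifest["seed"]),
        model=model,
        thresholds=thresholds,
        version=manifest.get("tool_version", "unknown"),
    )
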