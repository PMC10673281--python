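"""Dataset assembly, 70/30 splitting, SVM training and evaluation reports.

The evaluation surface mirrors how bioacoustic classifiers are usually
reported: a truth-by-prediction confusion matrix, accuracy as
100*trace/total, and error as its exact complement, computed separately
for a validation phase and a testing phase. Activity recognition is run
as three binary tasks (pupal moving vs resting, adult walking vs
resting, mating vs non-mating), with a 4-class mode also available.
An overall accuracy across tasks is reported under two aggregation
rules — pooled counts and the unweighted mean — since either is a
defensible summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .audio_dsp import band_power_report
from .bands import Activity, BandScheme, DEFAULT_BANDS

#: task name -> (positive label set, negative label set); None = all others
BINARY_TASKS = {
    "pupal": ({Activity.PUPA_MOVING}, {Activity.RESTING}),
    "adult": ({Activity.ADULT_WALKING}, {Activity.RESTING}),
    "mating": ({Activity.MATING}, None),
}


@dataclass
class LabeledFeatureSet:
    """Per-segment feature vectors with class labels and provenance."""

    features: np.ndarray
    labels: list
    ids: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (segments x features)")
        if not (len(self.labels) == len(self.ids) == self.features.shape[0]):
            raise ValueError("features, labels and ids must align")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing/non-finite values")

    def __len__(self) -> int:
        return self.features.shape[0]

    def subset(self, indices) -> "LabeledFeatureSet":
        indices = np.asarray(indices)
        return LabeledFeatureSet(
            features=self.features[indices],
            labels=[self.labels[i] for i in indices],
            ids=[self.ids[i] for i in indices],
            provenance=dict(self.provenance),
        )

    def relabel(self, mapping) -> "LabeledFeatureSet":
        """Apply a callable label -> new label (e.g. binarization)."""
        return LabeledFeatureSet(
            features=self.features,
            labels=[mapping(lbl) for lbl in self.labels],
            ids=list(self.ids),
            provenance=dict(self.provenance),
        )


def make_binary(dataset: LabeledFeatureSet, task: str) -> LabeledFeatureSet:
    """Project the 4-class dataset onto one of the binary tasks.

    ``pupal`` and ``adult`` keep only their positive class plus resting;
    ``mating`` keeps everything, relabelling non-mating segments.
    """
    positive, negative = BINARY_TASKS[task]
    if negative is None:
        return dataset.relabel(lambda l: l.value if l in positive else "non_mating")
    keep = [i for i, l in enumerate(dataset.labels) if l in positive | negative]
    return dataset.subset(keep).relabel(lambda l: l.value)


@dataclass(frozen=True)
class SplitSpec:
    """Train fraction, stratification flag and shuffle seed."""

    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def split_dataset(dataset: LabeledFeatureSet, spec: SplitSpec) -> tuple:
    """Disjoint, exhaustive train/test partition, deterministic under seed.

    Stratified mode allocates each class's train quota by the
    largest-remainder rule so per-class proportions match the requested
    fraction as closely as integer counts allow.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(dataset)
    if not spec.stratified:
        order = rng.permutation(n)
        n_train = int(round(spec.train_fraction * n))
        return dataset.subset(order[:n_train]), dataset.subset(order[n_train:])

    classes = sorted(set(dataset.labels), key=str)
    per_class = {c: [i for i, l in enumerate(dataset.labels) if l == c] for c in classes}
    for c, idx in per_class.items():
        if len(idx) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples; cannot stratify")

    quotas = np.array([spec.train_fraction * len(per_class[c]) for c in classes])
    floors = np.floor(quotas).astype(int)
    target = int(round(spec.train_fraction * n))
    remainder_order = np.argsort(-(quotas - floors), kind="stable")
    counts = floors.copy()
    for k in remainder_order[: max(target - floors.sum(), 0)]:
        counts[k] += 1

    train_idx, test_idx = [], []
    for c, n_train in zip(classes, counts):
        idx = np.array(per_class[c])[rng.permutation(len(per_class[c]))]
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))


@dataclass(frozen=True)
class SvmParams:
    """SVM hyperparameters; gamma="median" uses the median heuristic."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "median"
    seed: int = 0


def _median_heuristic_gamma(features: np.ndarray, rng: np.random.Generator) -> float:
    """1 / median pairwise squared distance, on standardized features."""
    n = len(features)
    sample = features[rng.permutation(n)[: min(n, 500)]]
    d2 = np.sum((sample[:, None, :] - sample[None, :, :]) ** 2, axis=-1)
    med = np.median(d2[np.triu_indices(len(sample), k=1)])
    return 1.0 / med if med > 0 else 1.0


@dataclass
class SvmModel:
    """A fitted standardize-then-SVC pipeline with its training metadata."""

    pipeline: Pipeline
    classes: list
    params: SvmParams
    gamma_value: float

    def predict(self, features: np.ndarray) -> list:
        if features.shape[1] != self.pipeline.named_steps["scale"].n_features_in_:
            raise ValueError("feature dimension does not match the trained model")
        return list(self.pipeline.predict(features))

    def save(self, path: str | Path) -> None:
        """Persist as a directory: meta.json + model.joblib."""
        import joblib

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "classes": [str(c) for c in self.classes],
            "params": {
                "kernel": self.params.kernel,
                "C": self.params.C,
                "gamma": self.params.gamma,
                "seed": self.params.seed,
            },
            "gamma_value": self.gamma_value,
        }
        with open(path / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)
        joblib.dump(self.pipeline, path / "model.joblib")

    @classmethod
    def load(cls, path: str | Path) -> "SvmModel":
        import joblib

        path = Path(path)
        with open(path / "meta.json") as fh:
            meta = json.load(fh)
        return cls(
            pipeline=joblib.load(path / "model.joblib"),
            classes=meta["classes"],
            params=SvmParams(**meta["params"]),
            gamma_value=meta["gamma_value"],
        )


def train_svm(train: LabeledFeatureSet, params: SvmParams = SvmParams()) -> SvmModel:
    """Fit a standardized SVM; deterministic under fixed params/seed."""
    classes = sorted(set(str(l) for l in train.labels))
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")
    scaler = StandardScaler().fit(train.features)
    if params.gamma == "median":
        rng = np.random.default_rng(params.seed)
        gamma = _median_heuristic_gamma(scaler.transform(train.features), rng)
    else:
        gamma = float(params.gamma)
    pipeline = Pipeline(
        [
            ("scale", scaler),
            ("svc", SVC(kernel=params.kernel, C=params.C, gamma=gamma,
                        random_state=params.seed)),
        ]
    )
    pipeline.fit(train.features, [str(l) for l in train.labels])
    return SvmModel(pipeline=pipeline, classes=classes, params=params, gamma_value=gamma)


@dataclass
class ConfusionMatrix:
    """Truth-by-prediction counts; rows = truth, columns = prediction."""

    classes: list
    counts: np.ndarray

    @classmethod
    def from_labels(cls, y_true, y_pred, classes=None) -> "ConfusionMatrix":
        y_true = [str(y) for y in y_true]
        y_pred = [str(y) for y in y_pred]
        if classes is None:
            classes = sorted(set(y_true) | set(y_pred))
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(classes=list(classes), counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * float(np.trace(self.counts)) / self.total

    def save_heatmap_png(self, path: str | Path, title: str = "Confusion matrix") -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 3.5))
        ax.imshow(self.counts, cmap="Blues")
        for (i, j), v in np.ndenumerate(self.counts):
            ax.text(j, i, str(v), ha="center", va="center")
        ax.set_xticks(range(len(self.classes)), self.classes, rotation=30)
        ax.set_yticks(range(len(self.classes)), self.classes)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.set_title(title)
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)


@dataclass
class ClassifierReport:
    """Accuracy/error pair with the underlying confusion matrix."""

    phase: str
    confusion: ConfusionMatrix
    task: str = ""

    @property
    def accuracy(self) -> float:
        return self.confusion.accuracy_percent

    @property
    def error(self) -> float:
        return 100.0 - self.accuracy

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "phase": self.phase,
            "accuracy_percent": self.accuracy,
            "error_percent": self.error,
            "classes": self.confusion.classes,
            "confusion": self.confusion.counts.tolist(),
            "total": self.confusion.total,
        }


def evaluate(model: SvmModel, data: LabeledFeatureSet, phase: str, task: str = "") -> ClassifierReport:
    """Confusion matrix, accuracy and error of ``model`` on ``data``."""
    if len(data) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    predictions = model.predict(data.features)
    classes = sorted(set(model.classes) | set(str(l) for l in data.labels))
    confusion = ConfusionMatrix.from_labels(data.labels, predictions, classes=classes)
    return ClassifierReport(phase=phase, confusion=confusion, task=task)


@dataclass(frozen=True)
class OverallAccuracy:
    """Cross-task summary under both defensible aggregation rules."""

    pooled_percent: float
    unweighted_mean_percent: float


def overall_accuracy(reports: list) -> OverallAccuracy:
    """Aggregate per-task reports as pooled counts and unweighted mean."""
    if not reports:
        raise ValueError("need at least one report")
    trace = sum(int(np.trace(r.confusion.counts)) for r in reports)
    total = sum(r.confusion.total for r in reports)
    return OverallAccuracy(
        pooled_percent=100.0 * trace / total,
        unweighted_mean_percent=float(np.mean([r.accuracy for r in reports])),
    )


def band_rule_classifier(segments, bands: BandScheme = DEFAULT_BANDS,
                         density_ratio_threshold: float = 2.0) -> list:
    """Transparent dominant-band baseline over raw audio segments.

    A segment is called ``resting`` unless its best band's power density
    exceeds ``density_ratio_threshold`` times the segment's overall
    spectral density (white background noise sits at ratio ~1);
    otherwise it gets the dominant band's activity.
    """
    out = []
    for seg in segments:
        report = band_power_report(seg, bands)
        nyquist = seg.sample_rate / 2.0
        low, high = bands[report.band]
        density_ratio = report.fractions[report.band] / ((high - low) / nyquist)
        out.append(report.band if density_ratio >= density_ratio_threshold else Activity.RESTING)
    return out
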