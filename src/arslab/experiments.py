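"""Experiment runner: negative-class design x task x classifier.

The central experimental design crosses how the negative ("other") class is
generated for the training and test sides:

* **FD/FD** — fixed 50/150 ms negatives on both sides (the conventional,
  duration-confounded design);
* **FD/VD** — train on fixed-duration negatives, test on Burr
  variable-duration negatives (exposes classifiers that learned duration);
* **VD/VD** — Burr variable-duration negatives on both sides (the
  realistic, duration-controlled design).

Each experiment is run on three tasks (crackle vs wheeze vs other; crackle
vs other; wheeze vs other), with feature selection fitted on the training
split only, and each classifier trained with several seeds; reports give
mean +/- std per metric per class plus confusion matrices.  A duration-only
control classifier (a decision tree on the annotated event duration alone)
quantifies how much of the performance is explained by duration leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .cnn import CNNSpec, TrainProtocol, build_cnn, predict_cnn, train_cnn
from .events import (
    ExcerptPolicy,
    event_counts,
    excerpt_event,
    generate_fixed_rge,
    generate_variable_rge,
)
from .evaluate import auc_binary, confusion, metrics_from_confusion, multiclass_accuracy
from .exceptions import ValidationError
from .features import DEFAULT_WINDOWS_MS, extract_feature_vector, feature_names
from .io_rsd import AnnotatedEvent, AudioRecording
from .selection import mrmr_rank, optimize_and_fit, positive_scores, select_subset
from .tf import STFTConfig, mel_spectrogram, normalize_image, stft_spectrogram

TASKS = ("3class", "2class_crackles", "2class_wheezes")
MODES = ("fixed", "variable")

#: task -> (positive labels kept, negative source labels per mode)
_TASK_NEGATIVES = {
    "3class": {"fixed": ("other50", "other150"), "variable": ("otherCrackle", "otherWheeze")},
    "2class_crackles": {"fixed": ("other50",), "variable": ("otherCrackle",)},
    "2class_wheezes": {"fixed": ("other150",), "variable": ("otherWheeze",)},
}
_TASK_POSITIVES = {
    "3class": ("crackle", "wheeze"),
    "2class_crackles": ("crackle",),
    "2class_wheezes": ("wheeze",),
}


@dataclass
class Corpus:
    """In-memory labelled corpus with a participant-level split."""

    recordings: list[tuple[AudioRecording, list[AnnotatedEvent]]]
    split: dict[str, str]  # participant_id -> train / test

    def side(self, side: str):
        return [
            (rec, evs) for rec, evs in self.recordings if self.split[rec.participant_id] == side
        ]


@dataclass(frozen=True)
class ExperimentConfig:
    """One cell of the design grid."""

    train_mode: str = "fixed"
    test_mode: str = "fixed"
    task: str = "3class"
    feature_subset: object = 100  # 10, 100 or "all"
    classifier: str = "svm_rbf"  # lda / svm_rbf / rusboost / duration_only / cnn_*
    n_seeds: int = 10
    budget: int = 30
    master_seed: int = 0
    windows_ms: tuple = DEFAULT_WINDOWS_MS

    def __post_init__(self):
        if self.train_mode not in MODES or self.test_mode not in MODES:
            raise ValidationError(f"modes must be in {MODES}")
        if self.task not in TASKS:
            raise ValidationError(f"task must be in {TASKS}")
        if self.n_seeds < 1:
            raise ValidationError("n_seeds must be >= 1")


@dataclass
class ExperimentReport:
    """Mean +/- std metric table over seeds plus confusion matrices."""

    config: ExperimentConfig
    classes: list[str]
    accuracy: np.ndarray  # (n_seeds,)
    per_class: dict[str, dict[str, np.ndarray]]  # class -> metric -> (n_seeds,)
    auc: np.ndarray | None  # binary tasks only
    confusions: list[np.ndarray]
    event_log: dict[str, dict[str, int]]

    def to_frame(self) -> pd.DataFrame:
        """Table shaped like the published result tables: one row, metric
        columns as percent ``mean +/- std`` to one decimal."""
        cols = {"Accuracy": self.accuracy}
        if self.auc is not None:
            cols["AUC"] = self.auc
        for cls in self.classes:
            if cls == "other" and len(self.classes) == 2:
                pass
            cols[f"F1_{cls}"] = self.per_class[cls]["f1"]
            cols[f"MCC_{cls}"] = self.per_class[cls]["mcc"]
        row = {
            k: f"{100 * np.mean(v):.1f} ± {100 * np.std(v):.1f}" for k, v in cols.items()
        }
        name = f"{self.config.classifier}_{self.config.feature_subset}"
        return pd.DataFrame([row], index=[name])

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy))


class FeatureCache:
    """Extract-once cache of event feature vectors keyed by event identity."""

    def __init__(self, windows_ms=DEFAULT_WINDOWS_MS, policy: ExcerptPolicy = ExcerptPolicy()):
        self.windows_ms = tuple(windows_ms)
        self.policy = policy
        self._store: dict[tuple, np.ndarray] = {}

    def names(self) -> list[str]:
        return feature_names(self.windows_ms)

    def get(self, rec: AudioRecording, ev: AnnotatedEvent) -> np.ndarray:
        key = (rec.recording_id, round(ev.start, 6), round(ev.end, 6))
        if key not in self._store:
            wave = excerpt_event(rec, ev, self.policy)
            self._store[key] = extract_feature_vector(wave, self.windows_ms, rate=rec.rate)
        return self._store[key]


def build_events_for_side(
    corpus: Corpus,
    side: str,
    mode: str,
    master_seed: int,
    rge_counts: dict | None = None,
) -> list[tuple[AudioRecording, AnnotatedEvent]]:
    """Annotated ARS events plus generated negatives for one split side.

    By default the number of generated negatives in each recording matches
    its ARS counts (short negatives = number of crackles, long negatives =
    number of wheezes), which keeps class sizes comparable across modes and
    makes the duration-matched control exact.
    """
    out = []
    for rec, events in corpus.side(side):
        ars = [e for e in events if e.label in ("crackle", "wheeze")]
        n_c = sum(e.label == "crackle" for e in ars)
        n_w = sum(e.label == "wheeze" for e in ars)
        if rge_counts is not None:
            n_short, n_long = rge_counts["short"], rge_counts["long"]
        else:
            n_short, n_long = n_c, n_w
        if mode == "fixed":
            rge = generate_fixed_rge(rec, ars, {0.050: n_short, 0.150: n_long}, master_seed)
        else:
            rge = generate_variable_rge(rec, ars, n_short, n_long, seed=master_seed)
        out.extend((rec, e) for e in ars + rge)
    return out


def task_label(ev_label: str, task: str, mode: str) -> str | None:
    """Map a raw event label onto the task's label set (None = excluded)."""
    if ev_label in _TASK_POSITIVES[task]:
        return ev_label
    if ev_label in _TASK_NEGATIVES[task][mode]:
        return "other"
    return None


def _assemble(pairs, task, mode, cache: FeatureCache | None):
    X, y, durations = [], [], []
    for rec, ev in pairs:
        lab = task_label(ev.label, task, mode)
        if lab is None:
            continue
        y.append(lab)
        durations.append(ev.duration)
        if cache is not None:
            X.append(cache.get(rec, ev))
    y = np.array(y)
    X = np.vstack(X) if cache is not None else np.array(durations)[:, None]
    return X, y, np.array(durations)


def _fit_predict_classical(cfg, Xtr, ytr, Xte, seed):
    if cfg.classifier == "duration_only":
        model = DecisionTreeClassifier(max_depth=6, random_state=seed)
        model.fit(Xtr, ytr)
        result_params = {}
    else:
        res = optimize_and_fit(cfg.classifier, Xtr, ytr, budget=cfg.budget, seed=seed)
        model, result_params = res.model, res.params
    return model, model.predict(Xte), result_params


def run_experiment(
    cfg: ExperimentConfig,
    corpus: Corpus,
    cache: FeatureCache | None = None,
    rge_counts: dict | None = None,
) -> ExperimentReport:
    """Run one experiment cell end to end.

    Builds the event sets for each side with the configured negative-class
    mode, extracts features (through the shared ``cache`` so adventitious
    events are featurized once across experiments), ranks features with MRMR
    on the training split only, trains ``n_seeds`` seeded classifiers, and
    evaluates each on the test split.
    """
    train_pids = {p for p, s in corpus.split.items() if s == "train"}
    test_pids = {p for p, s in corpus.split.items() if s == "test"}
    if train_pids & test_pids:
        raise ValidationError("train/test participants overlap")

    duration_only = cfg.classifier == "duration_only"
    if cache is None and not duration_only:
        cache = FeatureCache(cfg.windows_ms)
    feat_cache = None if duration_only else cache

    train_pairs = build_events_for_side(corpus, "train", cfg.train_mode, cfg.master_seed, rge_counts)
    test_pairs = build_events_for_side(corpus, "test", cfg.test_mode, cfg.master_seed, rge_counts)
    Xtr, ytr, _ = _assemble(train_pairs, cfg.task, cfg.train_mode, feat_cache)
    Xte, yte, _ = _assemble(test_pairs, cfg.task, cfg.test_mode, feat_cache)

    classes = sorted(set(ytr))
    if set(ytr) != set(yte) or len(classes) < 2:
        raise ValidationError("every task class must be present in both splits")

    if not duration_only:
        subset = cfg.feature_subset
        if subset == "all" or subset is None:
            sel = np.arange(Xtr.shape[1])
        else:
            ranking = mrmr_rank(Xtr, ytr, top_k=int(subset))
            sel = select_subset(ranking, int(subset))
        Xtr, Xte = Xtr[:, sel], Xte[:, sel]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd

    is_binary = cfg.task != "3class"
    pos_class = _TASK_POSITIVES[cfg.task][0] if is_binary else None

    acc, aucs, confs = [], [], []
    per_class = {c: {m: [] for m in ("precision", "sensitivity", "f1", "mcc")} for c in classes}
    for s in range(cfg.n_seeds):
        seed = cfg.master_seed * 1000 + s
        model, pred, _ = _fit_predict_classical(cfg, Xtr, ytr, Xte, seed)
        cm = confusion(yte, pred, classes)
        confs.append(cm)
        acc.append(multiclass_accuracy(cm))
        for i, c in enumerate(classes):
            m = metrics_from_confusion(cm, i)
            for k in per_class[c]:
                per_class[c][k].append(m[k])
        if is_binary:
            try:
                scores = positive_scores(model, Xte, pos_class)
                aucs.append(auc_binary(scores, yte == pos_class))
            except Exception:
                pass

    log = {
        "train": event_counts([e for _, e in train_pairs]),
        "test": event_counts([e for _, e in test_pairs]),
    }
    return ExperimentReport(
        config=cfg,
        classes=classes,
        accuracy=np.array(acc),
        per_class={c: {k: np.array(v) for k, v in d.items()} for c, d in per_class.items()},
        auc=np.array(aucs) if aucs else None,
        confusions=confs,
        event_log=log,
    )


# --------------------------------------------------------------------------
# CNN route
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageConfig:
    """Image extraction settings for the CNN route (canonical defaults give
    1 x 247 x 257 spectrograms and 1 x 247 x 64 mel spectrograms)."""

    stft: STFTConfig = field(default_factory=STFTConfig)
    n_mels: int = 64
    policy: ExcerptPolicy = field(default_factory=ExcerptPolicy)


def event_images(
    pairs, task, mode, img_cfg: ImageConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized (spectrogram, mel) image tensors and labels for the events."""
    specs, mels, labels = [], [], []
    for rec, ev in pairs:
        lab = task_label(ev.label, task, mode)
        if lab is None:
            continue
        wave = excerpt_event(rec, ev, img_cfg.policy)
        spec = stft_spectrogram(wave, img_cfg.stft, rec.rate)
        mel = mel_spectrogram(spec, img_cfg.n_mels)
        specs.append(normalize_image(spec).as_tensor())
        mels.append(normalize_image(mel).as_tensor())
        labels.append(lab)
    return np.stack(specs), np.stack(mels), np.array(labels)


def run_cnn_experiment(
    cfg: ExperimentConfig,
    corpus: Corpus,
    img_cfg: ImageConfig = ImageConfig(),
    protocol: TrainProtocol = TrainProtocol(),
    conv_filters: tuple = (16, 32, 64),
    dense_units: int = 64,
    rge_counts: dict | None = None,
) -> ExperimentReport:
    """CNN counterpart of :func:`run_experiment`.

    ``cfg.classifier`` selects the input configuration: ``cnn_dual`` (both
    images), ``cnn_spectrogram`` or ``cnn_mel``.
    """
    if cfg.classifier not in ("cnn_dual", "cnn_spectrogram", "cnn_mel"):
        raise ValidationError("run_cnn_experiment requires a cnn_* classifier")
    train_pairs = build_events_for_side(corpus, "train", cfg.train_mode, cfg.master_seed, rge_counts)
    test_pairs = build_events_for_side(corpus, "test", cfg.test_mode, cfg.master_seed, rge_counts)
    sp_tr, mel_tr, ytr = event_images(train_pairs, cfg.task, cfg.train_mode, img_cfg)
    sp_te, mel_te, yte = event_images(test_pairs, cfg.task, cfg.test_mode, img_cfg)
    if cfg.classifier == "cnn_dual":
        Xtr, Xte = [sp_tr, mel_tr], [sp_te, mel_te]
    elif cfg.classifier == "cnn_spectrogram":
        Xtr, Xte = [sp_tr], [sp_te]
    else:
        Xtr, Xte = [mel_tr], [mel_te]
    classes = sorted(set(ytr))
    shapes = tuple(tuple(x.shape[1:]) for x in Xtr)
    is_binary = cfg.task != "3class"
    pos_class = _TASK_POSITIVES[cfg.task][0] if is_binary else None

    acc, aucs, confs = [], [], []
    per_class = {c: {m: [] for m in ("precision", "sensitivity", "f1", "mcc")} for c in classes}
    for s in range(cfg.n_seeds):
        seed = cfg.master_seed * 1000 + s
        spec = CNNSpec(shapes, len(classes), conv_filters=conv_filters, dense_units=dense_units)
        model = build_cnn(spec, seed=seed)
        proto = TrainProtocol(
            epochs=protocol.epochs,
            batch_size=protocol.batch_size,
            learning_rate=protocol.learning_rate,
            patience=protocol.patience,
            val_fraction=protocol.val_fraction,
            seed=seed,
        )
        train_cnn(model, Xtr, ytr, proto)
        pred, proba = predict_cnn(model, Xte)
        cm = confusion(yte, pred, classes)
        confs.append(cm)
        acc.append(multiclass_accuracy(cm))
        for i, c in enumerate(classes):
            m = metrics_from_confusion(cm, i)
            for k in per_class[c]:
                per_class[c][k].append(m[k])
        if is_binary:
            pos_idx = classes.index(pos_class)
            aucs.append(auc_binary(proba[:, pos_idx], yte == pos_class))
    log = {
        "train": event_counts([e for _, e in train_pairs]),
        "test": event_counts([e for _, e in test_pairs]),
    }
    return ExperimentReport(
        config=cfg,
        classes=classes,
        accuracy=np.array(acc),
        per_class={c: {k: np.array(v) for k, v in d.items()} for c, d in per_class.items()},
        auc=np.array(aucs) if aucs else None,
        confusions=confs,
        event_log=log,
    )


__all__ = [
    "TASKS",
    "MODES",
    "Corpus",
    "ExperimentConfig",
    "ExperimentReport",
    "FeatureCache",
    "ImageConfig",
    "build_events_for_side",
    "task_label",
    "event_images",
    "run_experiment",
    "run_cnn_experiment",
]
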