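"""Sequence classification of preictal vs interictal state.

Rolling windows of ``T`` consecutive 20-s epoch feature vectors (default
T = 15, i.e. 5 minutes of history ending at the labeled epoch) are scored by
a sequence classifier.  The reference model is a numpy ConvLSTM
(:mod:`szforecast.convlstm`); classical baselines (logistic regression,
random forest, SVM, k-NN, MLP) run on the flattened window through the same
interface, and further architectures can be registered as plugins.

Evaluation uses subject-stratified nested k-fold cross-validation: the outer
loop holds out each test split once; within a fold the remaining subjects
are split into training and validation sets (3:1, i.e. 67.5%/22.5%/10% of
subjects at k=10), the validation set serving early stopping only.
Standardization is fit on training subjects only, and transposition
augmentation is applied to training folds only, with augmented copies
inheriting the parent subject's fold assignment — no test subject's data
ever touches training.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

from .convlstm import ConvLSTMNet, NetConfig, fit_network
from .features import FeatureSet, augmented_feature_views


@dataclass
class SubjectFeatures:
    """One subject's labeled, featurized epoch timeline."""

    subject_id: str
    epochs: pd.DataFrame  # start_s, epoch_len_s, label, censored
    fset: FeatureSet
    events: list[tuple[float, float]]  # merged consensus seizure events
    raw_events: list[tuple[float, float]]  # unmerged consensus events
    has_seizures: bool
    record_end_s: float

    @property
    def X(self) -> np.ndarray:
        return self.fset.X

    def augmented(self) -> list[np.ndarray]:
        return augmented_feature_views(self.fset)


@dataclass
class TrainConfig:
    arch: str = "convlstm"
    seq_len: int = 15  # 5 min of 20-s epochs, matching the preictal span
    conv_channels: tuple[int, ...] = (16, 32)
    hidden: int = 32
    dropout: float = 0.2
    lr: float = 3e-3
    batch_size: int = 256
    max_epochs: int = 30
    patience: int = 5
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_len < 1:
            raise ValueError("seq_len must be >= 1")


@dataclass
class FoldPlan:
    """Per-fold subject assignment; each subject is tested exactly once."""

    folds: list[dict[str, list[str]]]
    seed: int

    def validate(self) -> None:
        tested: list[str] = []
        for fold in self.folds:
            parts = [set(fold[s]) for s in ("train", "val", "test")]
            for i in range(3):
                for j in range(i + 1, 3):
                    if parts[i] & parts[j]:
                        raise ValueError("a subject appears in two splits of one fold")
            tested.extend(fold["test"])
        if len(tested) != len(set(tested)):
            raise ValueError("a subject appears in more than one test split")


def make_fold_plan(
    subject_ids: list[str],
    has_seizures: dict[str, bool],
    k: int = 10,
    fractions: tuple[float, float, float] = (0.675, 0.225, 0.10),
    seed: int = 0,
) -> FoldPlan:
    """Subject-stratified nested k-fold plan.

    Test splits partition the cohort (one k-th each, stratified on the
    has-seizure flag); the remaining subjects are split train/validation in
    the ratio ``fractions[0] : fractions[1]``, again stratified.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = np.asarray(subject_ids)
    flags = np.asarray([bool(has_seizures[s]) for s in subject_ids])
    if len(ids) < k:
        raise ValueError(f"{len(ids)} subjects cannot fill k={k} folds; reduce k")
    if min((~flags).sum(), flags.sum()) < 1:
        raise ValueError("need subjects both with and without seizures to stratify")

    rng = np.random.default_rng(seed)

    def stratified_split(pool: np.ndarray, n_groups: int) -> list[np.ndarray]:
        groups: list[list] = [[] for _ in range(n_groups)]
        for stratum in (True, False):
            members = pool[np.asarray([has_seizures[s] for s in pool]) == stratum]
            members = members[rng.permutation(len(members))]
            for i, s in enumerate(members):
                groups[i % n_groups].append(s)
        return [np.asarray(g) for g in groups]

    test_splits = stratified_split(ids, k)
    # rotate so fold sizes differ by at most one subject
    folds = []
    val_frac = fractions[1] / (fractions[0] + fractions[1])
    for fi in range(k):
        test = sorted(test_splits[fi].tolist())
        rest = np.asarray([s for s in subject_ids if s not in test])
        n_val = max(1, int(round(val_frac * len(rest))))
        val_groups = stratified_split(rest, int(np.ceil(len(rest) / n_val)))
        val = sorted(val_groups[0].tolist())[:n_val]
        train = sorted(s for s in rest if s not in val)
        if not train:
            raise ValueError("fold has an empty training split; reduce k")
        folds.append({"train": train, "val": val, "test": test})
    plan = FoldPlan(folds=folds, seed=seed)
    plan.validate()
    return plan


@dataclass
class PredictionTrace:
    """Per-subject preictal-probability series on the epoch grid.

    ``preictal_prob`` is NaN during the burn-in period (the first T-1
    epochs, where the sequence model lacks history).
    """

    subject_id: str
    epoch_end_times_s: np.ndarray
    preictal_prob: np.ndarray
    burn_in_mask: np.ndarray  # True where no prediction is available

    def __post_init__(self) -> None:
        valid = self.preictal_prob[~self.burn_in_mask]
        if valid.size and ((valid < 0).any() or (valid > 1).any()):
            raise ValueError("probabilities outside [0, 1]")


@dataclass
class SequenceDataset:
    windows: np.ndarray  # (n, T, F)
    labels: np.ndarray  # 1 preictal, 0 interictal, -1 other
    subject_ids: np.ndarray
    end_times_s: np.ndarray

    @property
    def trainable(self) -> np.ndarray:
        return self.labels >= 0


LABEL_CODE = {"preictal": 1, "interictal": 0, "ictal": -1, "excluded": -1}


def _subject_windows(
    X: np.ndarray, epochs: pd.DataFrame, T: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = X.shape[0]
    if n < T:
        return (
            np.empty((0, T, X.shape[1])),
            np.empty(0, dtype=int),
            np.empty(0),
        )
    idx = np.arange(T)[None, :] + np.arange(n - T + 1)[:, None]
    windows = X[idx]
    lab = epochs["label"].astype(str).map(LABEL_CODE).to_numpy()[T - 1 :]
    ends = (epochs["start_s"] + epochs["epoch_len_s"]).to_numpy()[T - 1 :]
    return windows, lab, ends


def build_sequences(
    subjects: list[SubjectFeatures],
    T: int,
    feature_matrices: dict[str, list[np.ndarray]] | None = None,
) -> SequenceDataset:
    """One window per non-burn-in epoch, never crossing subjects.

    ``feature_matrices`` optionally supplies alternative (e.g. augmented)
    feature matrices per subject; each extra matrix contributes an extra
    set of windows carrying the parent subject's ID.
    """
    ws, ls, ss, es = [], [], [], []
    for subj in subjects:
        mats = [subj.X]
        if feature_matrices and subj.subject_id in feature_matrices:
            mats += feature_matrices[subj.subject_id]
        for X in mats:
            w, lab, ends = _subject_windows(X, subj.epochs, T)
            ws.append(w)
            ls.append(lab)
            ss.append(np.full(len(lab), subj.subject_id, dtype=object))
            es.append(ends)
    if not ws:
        raise ValueError("no subjects produced windows")
    return SequenceDataset(
        windows=np.concatenate(ws),
        labels=np.concatenate(ls),
        subject_ids=np.concatenate(ss),
        end_times_s=np.concatenate(es),
    )


@dataclass
class Standardizer:
    mean: np.ndarray
    std: np.ndarray
    fit_subjects: tuple[str, ...]

    @classmethod
    def fit(cls, subjects: list[SubjectFeatures]) -> "Standardizer":
        X = np.concatenate([s.X for s in subjects])
        std = X.std(axis=0)
        return cls(
            mean=X.mean(axis=0),
            std=np.where(std > 0, std, 1.0),
            fit_subjects=tuple(sorted(s.subject_id for s in subjects)),
        )

    def apply(self, W: np.ndarray) -> np.ndarray:
        return (W - self.mean) / self.std


@dataclass
class ModelHandle:
    arch: str
    model: object
    scaler: Standardizer
    cfg: TrainConfig
    n_features: int
    feature_names: list[str]

    def predict_window_proba(self, W: np.ndarray) -> np.ndarray:
        Z = self.scaler.apply(W)
        if self.arch in ("convlstm", "lstm"):
            return self.model.predict_proba(Z)
        flat = Z.reshape(Z.shape[0], -1)
        return self.model.predict_proba(flat)[:, 1]


#: plugin registry: arch name -> callable(cfg, n_features) -> sklearn-style
#: estimator with fit(X, y) / predict_proba on flattened windows
CLASSIFIER_PLUGINS: dict[str, Callable] = {}


def register_classifier(name: str, factory: Callable) -> None:
    CLASSIFIER_PLUGINS[name] = factory


def _sklearn_baseline(arch: str, cfg: TrainConfig):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    if arch == "logistic":
        return LogisticRegression(max_iter=2000, class_weight="balanced")
    if arch == "random_forest":
        return RandomForestClassifier(
            n_estimators=200, class_weight="balanced", random_state=cfg.seed
        )
    if arch == "svm":
        return SVC(probability=True, class_weight="balanced", random_state=cfg.seed)
    if arch == "knn":
        return KNeighborsClassifier(n_neighbors=15)
    if arch == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(64,), max_iter=500, random_state=cfg.seed
        )
    raise NotImplementedError(
        f"architecture {arch!r} has no native implementation; register it "
        "via szforecast.forecaster.register_classifier"
    )


def train(
    train_ds: SequenceDataset,
    val_ds: SequenceDataset,
    scaler: Standardizer,
    cfg: TrainConfig,
    feature_names: list[str] | None = None,
) -> ModelHandle:
    """Fit the configured classifier on trainable (preictal/interictal)
    windows; the validation set drives early stopping for the sequence nets."""
    tr = train_ds.trainable
    va = val_ds.trainable
    Xtr = scaler.apply(train_ds.windows[tr])
    ytr = train_ds.labels[tr].astype(float)
    if len(np.unique(ytr)) < 2:
        raise ValueError("training windows contain a single class")
    n_features = Xtr.shape[2]
    if cfg.arch in ("convlstm", "lstm"):
        net_cfg = NetConfig(
            n_features=n_features,
            seq_len=cfg.seq_len,
            conv_channels=cfg.conv_channels if cfg.arch == "convlstm" else (),
            hidden=cfg.hidden,
            dropout=cfg.dropout,
        )
        rng = np.random.default_rng(cfg.seed)
        net = ConvLSTMNet(net_cfg, rng)
        Xva = scaler.apply(val_ds.windows[va])
        yva = val_ds.labels[va].astype(float)
        fit_network(
            net, Xtr, ytr, Xva, yva,
            lr=cfg.lr, batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
            patience=cfg.patience, seed=cfg.seed,
        )
        model = net
    else:
        factory = CLASSIFIER_PLUGINS.get(cfg.arch)
        model = factory(cfg, n_features) if factory else _sklearn_baseline(cfg.arch, cfg)
        model.fit(Xtr.reshape(Xtr.shape[0], -1), ytr)
    return ModelHandle(
        arch=cfg.arch,
        model=model,
        scaler=scaler,
        cfg=cfg,
        n_features=n_features,
        feature_names=feature_names or [],
    )


def predict_trace(handle: ModelHandle, subj: SubjectFeatures) -> PredictionTrace:
    """Continuous preictal-probability trace for one subject.

    Every non-burn-in epoch gets a probability, including epochs labeled
    excluded or ictal — the alarm system needs an unbroken timeline.
    """
    if subj.X.shape[1] != handle.n_features:
        names = handle.feature_names
        raise ValueError(
            f"feature schema mismatch: model expects {handle.n_features} "
            f"columns, subject has {subj.X.shape[1]}"
            + (f" (first model column: {names[0]!r})" if names else "")
        )
    T = handle.cfg.seq_len
    n = subj.X.shape[0]
    probs = np.full(n, np.nan)
    burn = np.ones(n, dtype=bool)
    if n >= T:
        w, _, _ = _subject_windows(subj.X, subj.epochs, T)
        probs[T - 1 :] = handle.predict_window_proba(w)
        burn[T - 1 :] = False
    ends = (subj.epochs["start_s"] + subj.epochs["epoch_len_s"]).to_numpy()
    return PredictionTrace(subj.subject_id, ends, probs, burn)


def _ids_hash(ids: list[str]) -> str:
    return hashlib.sha256(",".join(sorted(ids)).encode()).hexdigest()[:16]


@dataclass
class FoldRecord:
    """Provenance of one fold, for leakage auditing."""

    fold: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    scaler_fit_ids: tuple[str, ...]
    augmented_parent_ids: tuple[str, ...]
    train_hash: str = ""
    test_hash: str = ""

    def __post_init__(self) -> None:
        self.train_hash = _ids_hash(list(self.train_ids))
        self.test_hash = _ids_hash(list(self.test_ids))

    def assert_no_leakage(self) -> None:
        touched = set(self.train_ids) | set(self.val_ids)
        touched |= set(self.scaler_fit_ids) | set(self.augmented_parent_ids)
        overlap = touched & set(self.test_ids)
        if overlap:
            raise AssertionError(f"test subjects leaked into training: {overlap}")


@dataclass
class CVResult:
    traces: dict[str, PredictionTrace]
    fold_metrics: pd.DataFrame
    fold_records: list[FoldRecord]
    failures: list[int] = field(default_factory=list)


def epoch_level_metrics(probs: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    out = {"auroc": np.nan, "auprc": np.nan, "f1": np.nan}
    if len(np.unique(labels)) == 2:
        out["auroc"] = float(roc_auc_score(labels, probs))
        out["auprc"] = float(average_precision_score(labels, probs))
        out["f1"] = float(f1_score(labels, (probs > 0.5).astype(int)))
    return out


def run_nested_cv(
    subjects: list[SubjectFeatures],
    cfg: TrainConfig,
    plan: FoldPlan,
) -> CVResult:
    """Outer loop over test splits; per fold: fit on the training split
    (with transposition augmentation), early-stop on validation, emit test
    traces and epoch-level preictal-vs-interictal metrics.

    Folds that fail to train are reported in ``failures`` with the others'
    results intact.
    """
    plan.validate()
    by_id = {s.subject_id: s for s in subjects}
    traces: dict[str, PredictionTrace] = {}
    rows = []
    records = []
    failures = []
    for fi, fold in enumerate(plan.folds):
        train_subj = [by_id[s] for s in fold["train"]]
        val_subj = [by_id[s] for s in fold["val"]]
        test_subj = [by_id[s] for s in fold["test"]]
        scaler = Standardizer.fit(train_subj)
        aug = (
            {s.subject_id: s.augmented() for s in train_subj}
            if cfg.augment
            else None
        )
        records.append(
            FoldRecord(
                fold=fi,
                train_ids=tuple(fold["train"]),
                val_ids=tuple(fold["val"]),
                test_ids=tuple(fold["test"]),
                scaler_fit_ids=scaler.fit_subjects,
                augmented_parent_ids=tuple(sorted(aug)) if aug else (),
            )
        )
        try:
            tr_ds = build_sequences(train_subj, cfg.seq_len, aug)
            va_ds = build_sequences(val_subj, cfg.seq_len)
            fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + fi})
            handle = train(tr_ds, va_ds, scaler, fold_cfg)
        except (ValueError, FloatingPointError):
            failures.append(fi)
            rows.append({"fold": fi, "auroc": np.nan, "auprc": np.nan,
                         "f1": np.nan, "failed": True})
            continue
        probs_all, labels_all = [], []
        for subj in test_subj:
            trace = predict_trace(handle, subj)
            traces[subj.subject_id] = trace
            lab = subj.epochs["label"].astype(str).map(LABEL_CODE).to_numpy()
            ok = (~trace.burn_in_mask) & (lab >= 0)
            probs_all.append(trace.preictal_prob[ok])
            labels_all.append(lab[ok])
        met = epoch_level_metrics(np.concatenate(probs_all), np.concatenate(labels_all))
        rows.append({"fold": fi, **met, "failed": False})
    df = pd.DataFrame(rows).set_index("fold")
    summary = pd.DataFrame(
        {
            "auroc": [df["auroc"].mean(), df["auroc"].sem()],
            "auprc": [df["auprc"].mean(), df["auprc"].sem()],
            "f1": [df["f1"].mean(), df["f1"].sem()],
        },
        index=["mean", "se"],
    )
    df = pd.concat([df, summary])
    return CVResult(traces=traces, fold_metrics=df, fold_records=records,
                    failures=failures)


def pooled_held_out_scores(
    result: CVResult, subjects: list[SubjectFeatures]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool (prob, label, subject) over all held-out trainable epochs."""
    by_id = {s.subject_id: s for s in subjects}
    probs, labels, sids = [], [], []
    for sid, trace in result.traces.items():
        subj = by_id[sid]
        lab = subj.epochs["label"].astype(str).map(LABEL_CODE).to_numpy()
        ok = (~trace.burn_in_mask) & (lab >= 0)
        probs.append(trace.preictal_prob[ok])
        labels.append(lab[ok])
        sids.append(np.full(int(ok.sum()), sid, dtype=object))
    return np.concatenate(probs), np.concatenate(labels), np.concatenate(sids)


def bootstrap_auroc_ci(
    probs: np.ndarray,
    labels: np.ndarray,
    subject_ids: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Subject-level bootstrap CI for the pooled AUROC."""
    rng = np.random.default_rng(seed)
    uniq = np.unique(subject_ids)
    groups = {s: (probs[subject_ids == s], labels[subject_ids == s]) for s in uniq}
    stats = []
    for _ in range(n_boot):
        pick = rng.choice(uniq, size=len(uniq), replace=True)
        p = np.concatenate([groups[s][0] for s in pick])
        l = np.concatenate([groups[s][1] for s in pick])
        if len(np.unique(l)) == 2:
            stats.append(roc_auc_score(l, p))
    alpha = (1 - level) / 2
    return (
        float(np.quantile(stats, alpha)),
        float(np.quantile(stats, 1 - alpha)),
    )
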