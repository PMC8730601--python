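"""Four-class cardiovascular state decoding (rest / D / NE / D+NE).

Wraps the dense(250)+LSTM(100) sequence network in the training recipe used
for state decoding: standardized 13-feature steps at 100 ms, per-step
labels (rest 4-109 s, infusion 109-214 s), Adam (learning rate 0.01,
first-moment decay 0.8, gradient clip 2, L2 0.0005), one 75 %-of-data batch
per epoch, early stop at 98 % training accuracy.  Evaluation is by repeated
cross-validation with 80/20 train-test splits at the recording level, with
baseline comparators (no-LSTM dense network, SVM, LDA), per-feature
ablation, and label-permutation chance levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .features import FeatureFrame, baseline_normalize
from .nn import DenseLSTMClassifier, DenseDenseClassifier

__all__ = [
    "CLASSES", "DecoderConfig", "LabeledSequenceSet", "EvalReport",
    "build_dataset", "train", "predict_stream", "StreamDecoder",
    "crossvalidate", "baselines", "feature_ablation", "update",
    "save_model", "load_model",
]

CLASSES = ("rest", "D", "NE", "D+NE")
_CLASS_IDX = {c: i for i, c in enumerate(CLASSES)}


@dataclass
class DecoderConfig:
    """Architecture and optimizer settings of the state decoder."""

    n_features: int = 13
    dense_units: int = 250
    dropout_dense: float = 0.50
    lstm_units: int = 100
    dropout_lstm: float = 0.25
    n_classes: int = 4
    lr: float = 0.01
    gradient_decay: float = 0.8      # Adam first-moment decay
    gradient_clip: float = 2.0
    l2: float = 0.0005
    batch_fraction: float = 0.75
    early_stop_acc: float = 0.98
    max_epochs: int = 500
    chunk_len: int = 100             # steps per training sequence (10 s)
    input_scale: float = 0.2         # fixed input gain keeping standardized
                                     # magnitudes in the gates' sensitive range
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.dropout_dense < 1.0 and 0.0 <= self.dropout_lstm < 1.0):
            raise ValueError("dropout rates must lie in [0, 1)")
        if not (0.0 < self.batch_fraction <= 1.0):
            raise ValueError("batch fraction must lie in (0, 1]")
        if min(self.dense_units, self.lstm_units, self.n_classes,
               self.chunk_len, self.max_epochs) <= 0:
            raise ValueError("counts must be positive")

    def make_model(self, arch: str = "lstm", seed: int | None = None):
        cls = DenseLSTMClassifier if arch == "lstm" else DenseDenseClassifier
        return cls(
            n_features=self.n_features, dense_units=self.dense_units,
            lstm_units=self.lstm_units, n_classes=self.n_classes,
            dropout_dense=self.dropout_dense, dropout_lstm=self.dropout_lstm,
            lr=self.lr, beta1=self.gradient_decay, clip=self.gradient_clip,
            l2=self.l2, batch_fraction=self.batch_fraction,
            early_stop_acc=self.early_stop_acc, max_epochs=self.max_epochs,
            input_scale=self.input_scale,
            seed=self.seed if seed is None else seed)


@dataclass
class LabeledSequenceSet:
    """Standardized per-recording step sequences with per-step labels."""

    sequences: list            # (T_i, n_features) float arrays
    labels: list               # (T_i,) int arrays; -1 = missing step
    record_states: list        # protocol state name per recording
    subject_ids: list
    n_features: int = 13

    def __len__(self):
        return len(self.sequences)

    def chunks(self, chunk_len: int):
        """Cut recordings into fixed-length training chunks.

        Returns (X (N, chunk_len, F), y (N, chunk_len), record_index (N,)).
        Chunks never span a recording boundary; trailing remainders are
        dropped.  Chunks that are entirely missing are skipped.
        """
        X, y, rid = [], [], []
        for r, (seq, lab) in enumerate(zip(self.sequences, self.labels)):
            for s in range(0, seq.shape[0] - chunk_len + 1, chunk_len):
                yy = lab[s:s + chunk_len]
                if (yy < 0).all():
                    continue
                X.append(seq[s:s + chunk_len])
                y.append(yy)
                rid.append(r)
        return (np.asarray(X, dtype=np.float32), np.asarray(y),
                np.asarray(rid))

    def subset(self, record_indices) -> "LabeledSequenceSet":
        idx = list(record_indices)
        return LabeledSequenceSet(
            sequences=[self.sequences[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            record_states=[self.record_states[i] for i in idx],
            subject_ids=[self.subject_ids[i] for i in idx],
            n_features=self.n_features)

    def drop_features(self, features) -> "LabeledSequenceSet":
        keep = [i for i in range(self.n_features) if i not in set(features)]
        return LabeledSequenceSet(
            sequences=[s[:, keep] for s in self.sequences],
            labels=list(self.labels), record_states=list(self.record_states),
            subject_ids=list(self.subject_ids), n_features=len(keep))


@dataclass
class EvalReport:
    """Cross-validated decoding performance.

    ``accuracy`` is the overall accuracy in the deployed sense: the average
    across the four classes of each class's one-vs-rest accuracy.
    ``step_accuracy`` is the plain fraction of steps classified correctly;
    ``per_class_sensitivity`` the diagonal of the row-normalized confusion.
    """

    confusion: np.ndarray            # (4, 4) row-normalized, rows = truth
    accuracy: float                  # average accuracy across classes
    per_class_sensitivity: np.ndarray
    step_accuracy: float = float("nan")
    fold_accuracies: list = field(default_factory=list)
    chance: dict | None = None       # {"mean":..., "sd":..., "values": [...]}
    extra: dict = field(default_factory=dict)

    @property
    def mean_sensitivity(self) -> float:
        return float(np.nanmean(self.per_class_sensitivity))

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "step_accuracy": self.step_accuracy,
            "per_class_sensitivity": self.per_class_sensitivity.tolist(),
            "fold_accuracies": list(map(float, self.fold_accuracies)),
            "chance": self.chance, "extra": self.extra,
        }


def build_dataset(frames: list[FeatureFrame], min_background: float = 30.0) -> LabeledSequenceSet:
    """Standardize each recording from its own background window and attach
    integer step labels (missing steps labeled -1)."""
    seqs, labs, states, subjects = [], [], [], []
    for fr in frames:
        _, z = baseline_normalize(fr, min_background=min_background)
        y = np.array([_CLASS_IDX.get(l, -1) for l in fr.labels])
        y[fr.missing] = -1
        z = np.nan_to_num(z, nan=0.0)
        seqs.append(z.astype(np.float32))
        labs.append(y)
        states.append(fr.meta.get("state", _majority_state(fr.labels)))
        subjects.append(fr.meta.get("subject_id", -1))
    return LabeledSequenceSet(seqs, labs, states, subjects,
                              n_features=frames[0].X.shape[1])


def _majority_state(labels) -> str:
    non_rest = [l for l in labels if l != "rest"]
    return non_rest[0] if non_rest else "rest"


def train(dataset: LabeledSequenceSet, config: DecoderConfig | None = None,
          arch: str = "lstm"):
    """Train the decoder on every chunk of the given recordings."""
    config = config or DecoderConfig()
    X, y, _ = dataset.chunks(config.chunk_len)
    model = config.make_model(arch=arch)
    model.fit(X, y)
    return model


@dataclass
class StreamDecoder:
    """Carries recurrent state across 100 ms steps within one recording."""

    model: DenseLSTMClassifier
    state: tuple = None
    ischemia_class: int = _CLASS_IDX["D+NE"]

    def __post_init__(self):
        if self.state is None:
            self.state = self.model.init_state()

    def reset(self):
        self.state = self.model.init_state()

    def step(self, z_vec: np.ndarray) -> dict:
        """One step: standardized 13-vector -> score vector / class / trigger
        score.  Scores softmax-normalize to 1 by construction."""
        probs, self.state = self.model.step(z_vec, self.state)
        return {
            "scores": probs,
            "class_index": int(np.argmax(probs)),
            "class_name": CLASSES[int(np.argmax(probs))],
            "ischemia_score": float(probs[self.ischemia_class]),
        }


def predict_stream(model, z_vec, state):
    """Functional single-step interface: returns (DecoderOutput dict, state)."""
    probs, state = model.step(z_vec, state)
    return {
        "scores": probs,
        "class_index": int(np.argmax(probs)),
        "class_name": CLASSES[int(np.argmax(probs))],
        "ischemia_score": float(probs[_CLASS_IDX["D+NE"]]),
    }, state


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _stratified_split(dataset, test_fraction, rng):
    by_state: dict[str, list[int]] = {}
    for i, s in enumerate(dataset.record_states):
        by_state.setdefault(s, []).append(i)
    test = []
    for s, idx in sorted(by_state.items()):
        idx = list(idx)
        rng.shuffle(idx)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test.extend(idx[:n_test])
    train_idx = [i for i in range(len(dataset)) if i not in set(test)]
    return train_idx, sorted(test)


def _eval_model(model, dataset, record_indices):
    """Per-step predictions on whole recordings (batch == streaming)."""
    y_true, y_pred = [], []
    for i in record_indices:
        seq = dataset.sequences[i][None, ...]
        P = model.predict_proba(seq)[0]
        pred = np.argmax(P, axis=-1)
        lab = dataset.labels[i]
        ok = lab >= 0
        y_true.append(lab[ok])
        y_pred.append(pred[ok])
    return np.concatenate(y_true), np.concatenate(y_pred)


def _report_from_preds(y_true, y_pred, n_classes=4):
    conf = np.zeros((n_classes, n_classes))
    for t, p in zip(y_true, y_pred):
        conf[t, p] += 1
    row = conf.sum(axis=1, keepdims=True)
    conf_norm = np.divide(conf, row, out=np.full_like(conf, np.nan), where=row > 0)
    step_acc = float(np.mean(y_true == y_pred))
    sens = np.array([conf_norm[i, i] for i in range(n_classes)])
    # overall accuracy = average of per-class one-vs-rest accuracies
    n = y_true.size
    ova = []
    for c in range(n_classes):
        tp = conf[c, c]
        fn = conf[c].sum() - tp
        fp = conf[:, c].sum() - tp
        ova.append((n - fn - fp) / n)
    acc = float(np.mean(ova))
    return conf_norm, acc, sens, step_acc


def crossvalidate(dataset: LabeledSequenceSet, config: DecoderConfig | None = None,
                  k: int = 10, test_fraction: float = 0.2, arch: str = "lstm",
                  seed: int = 0, model_factory=None) -> EvalReport:
    """k repeated 80/20 train-test splits at the recording level.

    Folds never share a recording between train and test; accuracy and the
    row-normalized confusion matrix aggregate over all folds' test steps.
    ``model_factory(train_set, fold_seed)`` may replace the network (used
    for the SVM/LDA baselines).
    """
    config = config or DecoderConfig()
    if len(dataset) < 2:
        raise ValueError("need at least 2 recordings")
    if len(dataset) < k and model_factory is None:
        raise ValueError(f"fewer recordings ({len(dataset)}) than folds ({k})")
    rng = np.random.default_rng(seed)
    all_true, all_pred, fold_accs = [], [], []
    for fold in range(k):
        tr, te = _stratified_split(dataset, test_fraction, rng)
        train_set = dataset.subset(tr)
        if model_factory is None:
            cfg_fold = DecoderConfig(**{**asdict(config),
                                        "seed": config.seed + 1000 * fold,
                                        "n_features": dataset.n_features})
            model = train(train_set, cfg_fold, arch=arch)
        else:
            model = model_factory(train_set, config.seed + 1000 * fold)
        y_true, y_pred = _eval_model(model, dataset, te)
        all_true.append(y_true); all_pred.append(y_pred)
        fold_accs.append(float(np.mean(y_true == y_pred)))
    y_true = np.concatenate(all_true); y_pred = np.concatenate(all_pred)
    conf, acc, sens, step_acc = _report_from_preds(y_true, y_pred, config.n_classes)
    return EvalReport(conf, acc, sens, step_accuracy=step_acc,
                      fold_accuracies=fold_accs)


class _StepClassifier:
    """Adapter giving sklearn per-step classifiers the model interface."""

    def __init__(self, est, max_train_steps=6000, seed=0):
        self.est = est
        self.max_train_steps = max_train_steps
        self.seed = seed

    def fit(self, train_set: LabeledSequenceSet):
        X = np.concatenate(train_set.sequences)
        y = np.concatenate(train_set.labels)
        ok = y >= 0
        X, y = X[ok], y[ok]
        if X.shape[0] > self.max_train_steps:
            idx = np.random.default_rng(self.seed).choice(
                X.shape[0], self.max_train_steps, replace=False)
            X, y = X[idx], y[idx]
        self.est.fit(X, y)
        return self

    def predict_proba(self, seq):
        B, T, F = seq.shape
        pred = self.est.predict(seq.reshape(B * T, F))
        P = np.zeros((B, T, 4))
        np.put_along_axis(P.reshape(B * T, 4), pred[:, None], 1.0, axis=1)
        return P


def baselines(dataset: LabeledSequenceSet, config: DecoderConfig | None = None,
              k: int = 10, seed: int = 0, which=("ann_no_lstm", "svm", "lda")) -> dict:
    """Comparator classifiers under the identical CV protocol.

    The no-LSTM network keeps the training recipe; the SVM and LDA operate
    on single step vectors (no temporal memory).
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.svm import SVC

    config = config or DecoderConfig()
    out = {}
    for name in which:
        if name == "ann_no_lstm":
            out[name] = crossvalidate(dataset, config, k=k, arch="dense", seed=seed)
        elif name == "svm":
            out[name] = crossvalidate(
                dataset, config, k=k, seed=seed,
                model_factory=lambda ts, s: _StepClassifier(
                    SVC(kernel="rbf", C=1.0), seed=s).fit(ts))
        elif name == "lda":
            out[name] = crossvalidate(
                dataset, config, k=k, seed=seed,
                model_factory=lambda ts, s: _StepClassifier(
                    LinearDiscriminantAnalysis(), seed=s).fit(ts))
        else:
            raise ValueError(f"unknown baseline {name!r}")
    return out


def feature_ablation(dataset: LabeledSequenceSet, config: DecoderConfig | None = None,
                     groups: dict | None = None, k: int = 3, seed: int = 0):
    """Accuracy loss from retraining without each feature (or group).

    ``groups`` maps a name to a list of 0-based feature indices; default is
    each of the 13 features alone.  Returns a list of dicts sorted by loss
    (largest first), with the reference accuracy in each entry.
    """
    config = config or DecoderConfig()
    if groups is None:
        groups = {f"f{i+1}": [i] for i in range(dataset.n_features)}
    if any(len(g) >= dataset.n_features for g in groups.values()):
        raise ValueError("cannot ablate every feature")
    ref = crossvalidate(dataset, config, k=k, seed=seed)
    rows = []
    for name, feats in groups.items():
        sub = dataset.drop_features(feats)
        cfg = DecoderConfig(**{**asdict(config), "n_features": sub.n_features})
        rep = crossvalidate(sub, cfg, k=k, seed=seed)
        rows.append({"group": name, "features": list(feats),
                     "accuracy": rep.accuracy,
                     "loss": ref.accuracy - rep.accuracy,
                     "reference_accuracy": ref.accuracy})
    rows.sort(key=lambda r: -r["loss"])
    return rows


def update(model, dataset: LabeledSequenceSet, config: DecoderConfig | None = None,
           mode: str = "warm"):
    """Online supervised updating with newly recorded data.

    ``warm`` continues training the existing weights on the new chunks;
    ``retrain`` starts from scratch on the same data.
    """
    config = config or DecoderConfig()
    if mode == "retrain":
        return train(dataset, config)
    if mode != "warm":
        raise ValueError(f"unknown update mode {mode!r}")
    X, y, _ = dataset.chunks(config.chunk_len)
    model.fit(X, y)
    return model


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(model, path):
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.params)
    meta = {"cfg": {k: (v if not isinstance(v, np.generic) else v.item())
                    for k, v in model.cfg.items()},
            "arch": "dense" if "W2" in model.params else "lstm"}
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path.with_suffix(".npz")


def load_model(path):
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cls = DenseDenseClassifier if meta["arch"] == "dense" else DenseLSTMClassifier
    model = cls(**{k: meta["cfg"][k] for k in (
        "n_features", "dense_units", "lstm_units", "n_classes",
        "dropout_dense", "dropout_lstm", "lr", "beta1", "clip", "l2",
        "batch_fraction", "early_stop_acc", "max_epochs", "input_scale", "seed")})
    with np.load(path.with_suffix(".npz")) as data:
        for key in model.params:
            model.params[key] = data[key].astype(model.dtype)
    return model
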