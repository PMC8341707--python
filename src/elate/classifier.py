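"""One-vs-all clone classification on top of the frozen encoder.

A small head — four fully connected layers of 30, 15, 10 and 1 nodes, Tanh
activations with dropout 0.1 after the second and third layers, and a
sigmoid output — is trained on the 30-dimensional embeddings with a binary
cross-entropy loss and the same optimizer settings as the autoencoder.  The
encoder weights stay frozen throughout: only the head's parameters move.
Class imbalance in the one-vs-all setting is handled by inverse-frequency
weighting of the loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from elate import _nn
from elate.autoencoder import TrainedAE, Z_DIM, embed
from elate.io_encoding import RepertoireSample, TCRClone


@dataclass
class LabeledSplit:
    """Clone-level train/test partition of labelled samples.

    The training fraction holds a fixed number of clones per sample (500 by
    default); everything else is test.  Labels are the sample categories.
    """

    train_clones: list[TCRClone]
    train_labels: list[str]
    test_clones: list[TCRClone]
    test_labels: list[str]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.train_labels))


@dataclass
class ClassifierHead:
    """Trained head network plus its target class and training history."""

    net: _nn.Sequential
    target_class: str
    history: dict[str, list[float]] = field(default_factory=dict)


def make_split(samples: list[RepertoireSample], per_sample: int = 500, seed: int = 0) -> LabeledSplit:
    """Seeded draw of ``per_sample`` clones per sample into train; rest test.

    A sample smaller than ``per_sample`` contributes all its clones to the
    training fraction.  Every class must keep at least one test clone.
    """
    if per_sample < 1:
        raise ValueError("per_sample must be >= 1")
    rng = np.random.default_rng(seed)
    train_c: list[TCRClone] = []
    train_y: list[str] = []
    test_c: list[TCRClone] = []
    test_y: list[str] = []
    for sample in samples:
        n = len(sample)
        take = min(per_sample, n)
        idx = set(rng.choice(n, size=take, replace=False).tolist())
        for i, clone in enumerate(sample.clones):
            if i in idx:
                train_c.append(clone)
                train_y.append(sample.category)
            else:
                test_c.append(clone)
                test_y.append(sample.category)
    for cls in sorted(set(train_y)):
        if cls not in test_y:
            raise ValueError(f"class {cls!r} has no test clones; lower per_sample")
    return LabeledSplit(train_c, train_y, test_c, test_y)


def _build_head(rng: np.random.Generator, dropout: float = 0.1) -> _nn.Sequential:
    return _nn.Sequential(
        [
            _nn.Dense(Z_DIM, 30, rng),
            _nn.Tanh(),
            _nn.Dense(30, 15, rng),
            _nn.Tanh(),
            _nn.Dropout(dropout, rng),
            _nn.Dense(15, 10, rng),
            _nn.Tanh(),
            _nn.Dropout(dropout, rng),
            _nn.Dense(10, 1, rng),
            _nn.Sigmoid(),
        ]
    )


def bce_loss(y: np.ndarray, p: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Binary cross-entropy, optionally per-example weighted, mean over batch."""
    p = np.clip(np.asarray(p, dtype=np.float64), 1e-12, 1.0 - 1e-12)
    y = np.asarray(y, dtype=np.float64)
    terms = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    if weights is not None:
        terms = terms * weights
    return float(terms.mean())


def train_classifier(
    encoder_model: TrainedAE,
    split: LabeledSplit,
    target_class: str,
    epochs: int = 100,
    batch_size: int = 50,
    learning_rate: float = 1e-4,
    validation_fraction: float = 0.1,
    patience: int = 20,
    seed: int = 0,
) -> ClassifierHead:
    """Train a one-vs-all head for ``target_class`` on frozen embeddings.

    The encoder is used only in inference mode to produce embeddings; its
    parameters are never touched.  Positive examples are the target class,
    negatives all other classes pooled, with inverse-frequency example
    weights balancing the BCE loss.  Early stopping monitors validation BCE.
    """
    y = np.array([1.0 if lbl == target_class else 0.0 for lbl in split.train_labels], dtype=np.float64)
    if y.min() == y.max():
        raise ValueError("training data contains a single class")
    x = embed(encoder_model, split.train_clones).astype(np.float32)
    # inverse-frequency weights, normalized to mean 1
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    w = np.where(y == 1.0, len(y) / (2.0 * n_pos), len(y) / (2.0 * n_neg))

    rng = np.random.default_rng(seed)
    head = _build_head(rng)
    opt = _nn.Adam(head.all_params, lr=learning_rate)

    n_val = int(round(validation_fraction * len(x)))
    perm = rng.permutation(len(x))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    history: dict[str, list[float]] = {"bce": []}
    if n_val:
        history["val_bce"] = []
    best_val = np.inf
    best_state = None
    stale = 0
    b = min(batch_size, len(tr_idx))
    for _ in range(epochs):
        order = tr_idx[rng.permutation(len(tr_idx))]
        ep_loss = 0.0
        n_batches = 0
        for start in range(0, len(order) - b + 1, b):
            idx = order[start : start + b]
            xb, yb, wb = x[idx], y[idx], w[idx]
            p = head.forward(xb, train=True)[:, 0]
            p = np.clip(p, 1e-7, 1.0 - 1e-7)
            ep_loss += bce_loss(yb, p, wb)
            # d(BCE)/dp, weighted, mean over batch
            grad = (wb * (p - yb) / (p * (1.0 - p)) / len(yb)).astype(np.float32)
            head.backward(grad[:, None])
            opt.step(head.all_grads)
            n_batches += 1
        history["bce"].append(ep_loss / max(n_batches, 1))
        if n_val:
            pv = head.forward(x[val_idx], train=False)[:, 0]
            val = bce_loss(y[val_idx], pv, w[val_idx])
            history["val_bce"].append(val)
            if val < best_val - 1e-9:
                best_val, best_state, stale = val, head.state(), 0
            else:
                stale += 1
                if stale >= patience:
                    break
    if best_state is not None:
        head.load_state(best_state)
    return ClassifierHead(net=head, target_class=target_class, history=history)


def predict(head: ClassifierHead, encoder_model: TrainedAE, clones: list[TCRClone]) -> np.ndarray:
    """Per-clone probability of the head's target class (dropout off)."""
    z = embed(encoder_model, clones).astype(np.float32)
    return head.net.forward(z, train=False)[:, 0]


def evaluate_auc(head: ClassifierHead, encoder_model: TrainedAE, split: LabeledSplit) -> float:
    """ROC AUC of the head on the test fraction, one-vs-all labels."""
    y = np.array([1 if lbl == head.target_class else 0 for lbl in split.test_labels])
    if y.min() == y.max():
        raise ValueError("test set contains a single class")
    scores = predict(head, encoder_model, split.test_clones)
    return float(roc_auc_score(y, scores))
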