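"""Distance-preserving CDR3 autoencoders (E, VE, EM, VEM) and embeddings.

The encoder maps the one-hot clone vector (dimension n) through fully
connected layers of 300, 100 and 30 nodes, each with Elu activation and
dropout 0.1; the 30-dimensional output is the clone's embedding.  The decoder
mirrors the encoder (30 -> 100 -> 300 -> n) and ends with a softmax applied
separately to every 21-block (and to the V block when V usage is encoded), so
each block of the reconstruction is a probability vector over symbols.

Four flavors share this architecture:

=====  ========  ==============================
model  V gene    distance-maintenance loss
=====  ========  ==============================
E      no        no (reconstruction MSE only)
VE     yes       no
EM     no        yes
VEM    yes       yes
=====  ========  ==============================

The distance-maintenance loss penalizes, over all pairs in a batch, the
difference between the Euclidean distance of the two embeddings and the
Euclidean distance of the corresponding one-hot inputs, pushing the embedding
toward a pairwise isometry of the input space.  Training uses Adam at
learning rate 1e-4 with a mean-squared-error reconstruction loss; dropout is
active only during training, so embeddings and reconstructions are
deterministic at inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from elate import _nn
from elate.io_encoding import (
    BLOCK,
    EncodingScheme,
    RepertoireSample,
    SchemeError,
    TCRClone,
    decode,
    encode_batch,
)

#: Embedding dimensionality (last encoder layer).
Z_DIM = 30


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int) -> None:
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass
class AEConfig:
    """Training configuration for every autoencoder flavor.

    ``dis_weight`` multiplies the per-pair-normalized distance loss, making
    the two loss terms scale-comparable across batch sizes; ``dis_squared``
    switches the distance loss to compare squared embedding distances against
    unsquared input distances (an alternative reading of the loss), the
    default compares unsquared Euclidean distances on both sides.
    """

    layer_sizes: tuple[int, ...] = (300, 100, Z_DIM)
    dropout: float = 0.1
    bottleneck_dropout: bool = False
    learning_rate: float = 1e-4
    batch_size: int = 50
    epochs: int = 300
    dis_weight: float = 1.0
    use_v: bool = False
    use_dis_loss: bool = False
    dis_squared: bool = False
    validation_fraction: float = 0.0
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layer_sizes[-1] != Z_DIM:
            raise ValueError(f"last encoder layer must have {Z_DIM} nodes")
        if self.dis_weight < 0:
            raise ValueError("dis_weight must be >= 0")
        if self.use_dis_loss and self.dis_weight == 0:
            raise ValueError("use_dis_loss requires dis_weight > 0")

    @classmethod
    def for_model(cls, model: str, **kwargs) -> "AEConfig":
        """Config for a named flavor: E, VE, EM or VEM."""
        model = model.upper()
        flags = {
            "E": dict(use_v=False, use_dis_loss=False),
            "VE": dict(use_v=True, use_dis_loss=False),
            "EM": dict(use_v=False, use_dis_loss=True),
            "VEM": dict(use_v=True, use_dis_loss=True),
        }
        if model not in flags:
            raise ValueError(f"unknown model {model!r}; expected one of E, VE, EM, VEM")
        return cls(**{**flags[model], **kwargs})

    @property
    def model_name(self) -> str:
        return ("V" if self.use_v else "") + "E" + ("M" if self.use_dis_loss else "")


@dataclass
class TrainedAE:
    """Encoder/decoder pair with its scheme, config and training history."""

    encoder: _nn.Sequential
    decoder: _nn.Sequential
    scheme: EncodingScheme
    config: AEConfig
    history: dict[str, list[float]] = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        weights = {f"enc_{i}": p for i, p in enumerate(self.encoder.all_params)}
        weights |= {f"dec_{i}": p for i, p in enumerate(self.decoder.all_params)}
        np.savez_compressed(out_dir / "weights.npz", **weights)
        sidecar = {
            "scheme": self.scheme.to_dict(),
            "config": asdict(self.config),
            "history": self.history,
            "stop_symbol_index": 20,
        }
        (out_dir / "model.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, out_dir: str | Path) -> "TrainedAE":
        out_dir = Path(out_dir)
        sidecar = json.loads((out_dir / "model.json").read_text())
        scheme = EncodingScheme.from_dict(sidecar["scheme"])
        cfg = sidecar["config"]
        cfg["layer_sizes"] = tuple(cfg["layer_sizes"])
        config = AEConfig(**cfg)
        model = build_autoencoder(scheme, config)
        with np.load(out_dir / "weights.npz") as data:
            model.encoder.load_state([data[f"enc_{i}"] for i in range(len(model.encoder.all_params))])
            model.decoder.load_state([data[f"dec_{i}"] for i in range(len(model.decoder.all_params))])
        model.history = sidecar["history"]
        return model


def _output_blocks(scheme: EncodingScheme) -> list[tuple[int, int]]:
    blocks = [(i * BLOCK, (i + 1) * BLOCK) for i in range(scheme.n_blocks)]
    if scheme.use_v:
        blocks.append((BLOCK * scheme.n_blocks, scheme.n))
    return blocks


def build_autoencoder(scheme: EncodingScheme, config: AEConfig) -> TrainedAE:
    """Assemble an untrained encoder/decoder pair for the scheme."""
    if config.use_v != scheme.use_v:
        raise SchemeError(
            f"config.use_v={config.use_v} but scheme has n_V={scheme.n_v}"
        )
    if (scheme.n - scheme.n_v) % BLOCK != 0:
        raise SchemeError("scheme dimension does not decompose into 21-blocks")
    rng = np.random.default_rng(config.seed)
    enc_layers: list[_nn.Layer] = []
    n_in = scheme.n
    for i, size in enumerate(config.layer_sizes):
        enc_layers += [_nn.Dense(n_in, size, rng), _nn.Elu()]
        # dropout sits between hidden layers; the 30-dim code itself is kept
        # intact unless explicitly requested, since noising the representation
        # consumed by every downstream analysis slows training markedly
        if i < len(config.layer_sizes) - 1 or config.bottleneck_dropout:
            enc_layers.append(_nn.Dropout(config.dropout, rng))
        n_in = size
    dec_layers: list[_nn.Layer] = []
    for size in config.layer_sizes[-2::-1]:
        dec_layers += [_nn.Dense(n_in, size, rng), _nn.Elu(), _nn.Dropout(config.dropout, rng)]
        n_in = size
    dec_layers += [_nn.Dense(n_in, scheme.n, rng), _nn.BlockSoftmax(_output_blocks(scheme))]
    return TrainedAE(
        encoder=_nn.Sequential(enc_layers),
        decoder=_nn.Sequential(dec_layers),
        scheme=scheme,
        config=config,
    )


# ---------------------------------------------------------------------------
# losses


def loss_mse(y: np.ndarray, y_hat: np.ndarray, component_reduction: str = "mean") -> float:
    """Reconstruction mean squared error.

    Averaged over the batch and, by the package's convention, also over
    vector components (``component_reduction="mean"``); ``"sum"`` gives the
    per-example summed squared error averaged over the batch only.
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    sq = (y - y_hat) ** 2
    if component_reduction == "mean":
        return float(sq.mean())
    if component_reduction == "sum":
        return float(sq.sum(axis=-1).mean())
    raise ValueError("component_reduction must be 'mean' or 'sum'")


def loss_dis(z: np.ndarray, d_b: np.ndarray, squared: bool = False, normalize: bool = False) -> float:
    """Distance-maintenance loss over all pairs of a batch.

    Sum over i<j of (d_z(i,j) - D_ij)^2 where d_z is the Euclidean distance
    between embeddings and D_ij the Euclidean distance between the one-hot
    inputs.  With ``squared=True`` the embedded distance enters squared (the
    alternative reading); with ``normalize=True`` the sum is divided by the
    number of pairs, the form used inside the training objective.
    """
    z = np.asarray(z, dtype=np.float64)
    b = z.shape[0]
    d_b = np.asarray(d_b, dtype=np.float64)
    if d_b.shape != (b, b):
        raise ValueError(f"distance matrix shape {d_b.shape} does not match batch size {b}")
    if b < 2:
        return 0.0
    iu = np.triu_indices(b, k=1)
    dz = pdist(z)
    if squared:
        dz = dz**2
    val = float(((dz - d_b[iu]) ** 2).sum())
    if normalize:
        val /= len(dz)
    return val


def _dis_grad(z: np.ndarray, d_b: np.ndarray, weight: float, squared: bool) -> tuple[np.ndarray, float]:
    """Gradient of weight * loss_dis/n_pairs with respect to z, plus the loss value."""
    b = z.shape[0]
    if b < 2:
        return np.zeros_like(z), 0.0
    z64 = z.astype(np.float64)
    dz = squareform(pdist(z64))
    n_pairs = b * (b - 1) / 2
    scale = weight / n_pairs
    if squared:
        err = dz**2 - d_b
        np.fill_diagonal(err, 0.0)
        coeff = 2.0 * err  # d/dz of (sq - D)^2 contributes 2*err * 2*(zi - zj)
        raw = float((err[np.triu_indices(b, k=1)] ** 2).sum())
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            coeff = np.where(dz > 0, (dz - d_b) / np.where(dz > 0, dz, 1.0), 0.0)
        np.fill_diagonal(coeff, 0.0)
        raw = float(((dz - d_b)[np.triu_indices(b, k=1)] ** 2).sum())
    grad = 2.0 * scale * (coeff.sum(axis=1, keepdims=True) * z64 - coeff @ z64)
    return grad.astype(np.float32), raw / n_pairs


# ---------------------------------------------------------------------------
# training


def _as_clones(data: Iterable[RepertoireSample] | Sequence[TCRClone]) -> list[TCRClone]:
    clones: list[TCRClone] = []
    for item in data:
        if isinstance(item, TCRClone):
            clones.append(item)
        else:
            clones.extend(item.clones)
    return clones


def train(
    data: Iterable[RepertoireSample] | Sequence[TCRClone],
    scheme: EncodingScheme,
    config: AEConfig,
    verbose: bool = False,
) -> TrainedAE:
    """Train an autoencoder on the pooled clones of ``data``.

    Minimizes the reconstruction MSE, plus ``dis_weight`` times the
    per-pair-normalized distance-maintenance loss for the EM/VEM flavors,
    with Adam at the configured learning rate.  The pairwise input-distance
    matrix of each batch is computed on the fly from the batch's one-hot
    rows (entry-wise identical to slicing a precomputed full-corpus distance
    matrix).  Reproducible bit-for-bit given ``config.seed``.

    With ``validation_fraction > 0`` a seeded tail of the corpus is held out
    and training stops early once the validation objective has not improved
    for ``patience`` epochs (the best parameters are restored).
    """
    clones = _as_clones(data)
    if not clones:
        raise ValueError("empty training set")
    model = build_autoencoder(scheme, config)
    x_all = encode_batch(clones, scheme)
    rng = np.random.default_rng(config.seed + 1)  # data order; init uses config.seed

    n_val = int(round(config.validation_fraction * len(x_all)))
    perm = rng.permutation(len(x_all))
    x_val = x_all[perm[:n_val]]
    x_train = x_all[perm[n_val:]]
    if len(x_train) == 0:
        raise ValueError("validation split leaves no training data")

    opt = _nn.Adam(model.encoder.all_params + model.decoder.all_params, lr=config.learning_rate)
    history: dict[str, list[float]] = {"mse": [], "dis": [], "total": []}
    if n_val:
        history["val_total"] = []
    best_val = np.inf
    best_state: tuple[list[np.ndarray], list[np.ndarray]] | None = None
    stale = 0

    n = x_train.shape[0]
    b = min(config.batch_size, n)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_mse = ep_dis = 0.0
        n_batches = 0
        for start in range(0, n - b + 1, b):
            xb = x_train[order[start : start + b]]
            zb = model.encoder.forward(xb, train=True)
            yb = model.decoder.forward(zb, train=True)
            diff = (yb - xb).astype(np.float32)
            mse = float((diff.astype(np.float64) ** 2).mean())
            grad_y = (2.0 / diff.size) * diff
            grad_z = model.decoder.backward(grad_y)
            dis_val = 0.0
            if config.use_dis_loss:
                d_b = squareform(pdist(xb.astype(np.float64)))
                g_dis, dis_val = _dis_grad(zb, d_b, config.dis_weight, config.dis_squared)
                grad_z = grad_z + g_dis
            model.encoder.backward(grad_z)
            opt.step(model.encoder.all_grads + model.decoder.all_grads)
            ep_mse += mse
            ep_dis += dis_val
            n_batches += 1
        ep_mse /= max(n_batches, 1)
        ep_dis /= max(n_batches, 1)
        total = ep_mse + config.dis_weight * ep_dis
        if not np.isfinite(total):
            raise DivergenceError(epoch)
        history["mse"].append(ep_mse)
        history["dis"].append(ep_dis)
        history["total"].append(total)
        if verbose and (epoch % 10 == 0 or epoch == config.epochs - 1):
            print(f"epoch {epoch:4d}  mse {ep_mse:.5f}  dis {ep_dis:.5f}")
        if n_val:
            val_total = _objective(model, x_val, config)
            history["val_total"].append(val_total)
            if val_total < best_val - 1e-9:
                best_val = val_total
                best_state = (model.encoder.state(), model.decoder.state())
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if best_state is not None:
        model.encoder.load_state(best_state[0])
        model.decoder.load_state(best_state[1])
    model.history = history
    return model


def _objective(model: TrainedAE, x: np.ndarray, config: AEConfig) -> float:
    z = model.encoder.forward(x, train=False)
    y = model.decoder.forward(z, train=False)
    total = loss_mse(x, y)
    if config.use_dis_loss:
        d = squareform(pdist(x.astype(np.float64)))
        total += config.dis_weight * loss_dis(z, d, squared=config.dis_squared, normalize=True)
    return total


# ---------------------------------------------------------------------------
# inference


def embed(model: TrainedAE, clones: Sequence[TCRClone]) -> np.ndarray:
    """Project clones to their 30-dimensional embeddings (dropout off)."""
    x = encode_batch(list(clones), model.scheme)
    return model.encoder.forward(x, train=False)


def reconstruct(model: TrainedAE, clones: Sequence[TCRClone]) -> list[tuple[str, str | None]]:
    """Decode the autoencoder's reconstruction of each clone."""
    x = encode_batch(list(clones), model.scheme)
    y = model.decoder.forward(model.encoder.forward(x, train=False), train=False)
    return [decode(row, model.scheme) for row in y]


def reconstruction_accuracy(model: TrainedAE, clones: Sequence[TCRClone], k: int = 0) -> float:
    """Fraction of clones reconstructed with <= k position mismatches.

    A reconstruction whose decoded length differs from the original is an
    error for every k; otherwise the error level is the number of differing
    positions.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    clones = list(clones)
    if not clones:
        raise ValueError("empty test set")
    good = 0
    for clone, (rec, _) in zip(clones, reconstruct(model, clones)):
        if len(rec) != len(clone.cdr3):
            continue
        mismatches = sum(a != b for a, b in zip(clone.cdr3, rec))
        if mismatches <= k:
            good += 1
    return good / len(clones)


def distance_correlation(model: TrainedAE, clones: Sequence[TCRClone]) -> tuple[float, float]:
    """Spearman rho (and p) between input-space and embedding-space distances.

    Computed over all unordered clone pairs: Euclidean distance between the
    one-hot vectors against Euclidean distance between the embeddings.
    """
    clones = list(clones)
    if len(clones) < 3:
        raise ValueError("need at least 3 clones")
    x = encode_batch(clones, model.scheme).astype(np.float64)
    z = embed(model, clones).astype(np.float64)
    dx = pdist(x)
    dz = pdist(z)
    if np.ptp(dx) == 0 or np.ptp(dz) == 0:
        raise ValueError("all pairwise distances identical; correlation undefined")
    rho, p = spearmanr(dx, dz)
    return float(rho), float(p)
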