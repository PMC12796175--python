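"""Five-class CNN for pressure-map QC with a side-label embedding.

The backbone is three convolutional blocks with 32, 64 and 128 filters;
each block stacks two 3x3 convolutions (batch-normalized, ReLU) and
ends with 2x2 max-pooling and spatial dropout, halving the canvas
64 -> 32 -> 16 -> 8.  The flattened 128*8*8 = 8192 feature vector is
concatenated with an 8-dimensional embedding of the integer side label
and classified by a two-layer head.  The map itself is consumed
*unregistered*; spatial invariance is left to the network.

Training uses class-frequency-inverse weighted cross-entropy and
class-balanced sampling, Adam (lr 1e-3), and early stopping on the
validation loss with patience 10; the checkpoint with the lowest
validation loss is retained.  Inputs are standardized with the mean and
standard deviation of the *training* pixels of the current fold only.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .dataio import Dataset
from .types import Side

N_CLASSES = 5
SIDE_INDEX = {Side.LEFT: 0, Side.RIGHT: 1}


@dataclass
class ModelConfig:
    filters: tuple = (32, 64, 128)
    conv_dropout: float = 0.25
    embedding_dim: int = 8
    head_hidden: int = 256
    head_dropout: float = 0.25
    n_classes: int = N_CLASSES


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 10
    #: minimum validation-loss improvement that resets the patience counter
    min_delta: float = 5e-3
    seed: int = 0
    balanced_sampling: bool = True
    weighted_loss: bool = True
    #: balanced draws per epoch; None uses the training-set size
    samples_per_epoch: int | None = 1024


@dataclass
class Prediction:
    probabilities: np.ndarray     # (5,)
    label: int
    is_outlier: bool


def compute_fold_stats(train_grids: np.ndarray) -> tuple[float, float]:
    """Scalar mean/sd over all training pixels of the current fold.

    Computed from training data only, so validation/test grids never
    leak into the standardization.
    """
    g = np.asarray(train_grids)
    if g.size == 0 or len(g) < 2:
        raise ValueError("need at least 2 training samples")
    sd = float(g.std())
    if sd < 1e-12:
        raise ValueError("zero-variance training data")
    return float(g.mean()), sd


class PlantarCNN:
    """The classifier network (see module docstring for the layout)."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)
        c = self.config
        self.blocks = []
        cin = 1
        for cout in c.filters:
            self.blocks.append([
                nn.Conv3x3(cin, cout, rng), nn.BatchNorm(cout), nn.ReLU(),
                nn.Conv3x3(cout, cout, rng), nn.BatchNorm(cout), nn.ReLU(),
                nn.MaxPool2x2(),
                nn.Dropout(c.conv_dropout, self._dropout_rng, channel=True),
            ])
            cin = cout
        self.flat_dim = c.filters[-1] * 8 * 8
        self.embedding = nn.Embedding(2, c.embedding_dim, rng)
        self.fc1 = nn.Dense(self.flat_dim + c.embedding_dim, c.head_hidden, rng)
        # balanced-concatenation init: the 8 embedding inputs are re-drawn
        # with fan-in = embedding_dim so the side signal is not drowned by
        # the 8192 convolutional features at initialization
        emb_std = np.sqrt(2.0 / c.embedding_dim)
        self.fc1.params["W"][self.flat_dim:, :] = (
            rng.standard_normal((c.embedding_dim, c.head_hidden))
            * emb_std).astype(nn.F32)
        self.bn_head = nn.BatchNorm(c.head_hidden)
        self.relu_head = nn.ReLU()
        self.drop_head = nn.Dropout(c.head_dropout, self._dropout_rng)
        self.fc2 = nn.Dense(c.head_hidden, c.n_classes, rng)

    def layers(self):
        for block in self.blocks:
            yield from block
        yield from (self.embedding, self.fc1, self.bn_head, self.relu_head,
                    self.drop_head, self.fc2)

    # -- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray, sides: np.ndarray | None = None,
                training: bool = False,
                embedding_override: np.ndarray | None = None) -> np.ndarray:
        """Logits for a batch.

        ``x`` is (n, 64, 64) standardized; ``sides`` integer codes
        (0 = left, 1 = right).  ``embedding_override`` replaces the
        embedding lookup with explicit vectors (used by the attribution
        backend, which differentiates along a continuous embedding
        path).
        """
        h = np.asarray(x, dtype=nn.F32)[..., None]       # NHWC, 1 channel
        for block in self.blocks:
            for layer in block:
                h = layer.forward(h, training)
        n = h.shape[0]
        flat = h.reshape(n, self.flat_dim)
        if embedding_override is not None:
            emb = np.asarray(embedding_override, dtype=nn.F32)
            self._emb_override = True
        else:
            emb = self.embedding.forward(np.asarray(sides), training)
            self._emb_override = False
        z = np.concatenate([flat, emb], axis=1)
        z = self.fc1.forward(z, training)
        z = self.bn_head.forward(z, training)
        z = self.relu_head.forward(z, training)
        z = self.drop_head.forward(z, training)
        return self.fc2.forward(z, training)

    def backward(self, dlogits: np.ndarray):
        """Backprop; returns (d_input_grid, d_embedding_vector)."""
        dz = self.fc2.backward(dlogits)
        dz = self.drop_head.backward(dz)
        dz = self.relu_head.backward(dz)
        dz = self.bn_head.backward(dz)
        dz = self.fc1.backward(dz)
        dflat, demb = dz[:, :self.flat_dim], dz[:, self.flat_dim:]
        if not self._emb_override:
            self.embedding.backward(demb)
        n = dflat.shape[0]
        dh = dflat.reshape(n, 8, 8, self.config.filters[-1])
        for block in reversed(self.blocks):
            for layer in reversed(block):
                dh = layer.backward(dh)
        return dh[..., 0], demb

    # -- checkpointing -------------------------------------------------
    def get_state(self) -> list:
        state = []
        for layer in self.layers():
            entry = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, nn.BatchNorm):
                entry["_rm"] = layer.running_mean.copy()
                entry["_rv"] = layer.running_var.copy()
            state.append(entry)
        return state

    def set_state(self, state: list) -> None:
        for layer, entry in zip(self.layers(), state):
            for k in layer.params:
                layer.params[k][...] = entry[k]
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean[...] = entry["_rm"]
                layer.running_var[...] = entry["_rv"]


def build_model(config: ModelConfig | None = None, seed: int = 0) -> PlantarCNN:
    return PlantarCNN(config, seed=seed)


# ---------------------------------------------------------------------
# training
# ---------------------------------------------------------------------
def class_weights(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """Weights inversely proportional to class frequency (mean 1)."""
    counts = np.bincount(labels, minlength=n_classes)
    if (counts == 0).any():
        missing = np.flatnonzero(counts == 0).tolist()
        raise ValueError(f"classes {missing} missing from training set")
    w = 1.0 / counts
    return w / w.mean()


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf


def _evaluate_loss(model, grids, sides, labels, weights, batch: int = 32):
    total, wsum = 0.0, 0.0
    w = weights[labels]
    for i in range(0, len(grids), batch):
        logits = model.forward(grids[i:i + batch], sides[i:i + batch],
                               training=False)
        probs = nn.softmax(logits.astype(np.float64))
        nll = -np.log(np.clip(probs[np.arange(len(logits)),
                                    labels[i:i + batch]], 1e-12, None))
        total += (w[i:i + batch] * nll).sum()
        wsum += w[i:i + batch].sum()
    return total / wsum


def train(model: PlantarCNN, train_data, val_data,
          config: TrainConfig | None = None) -> TrainHistory:
    """Train with balanced sampling and weighted CE; keep the best
    validation checkpoint.

    ``train_data`` / ``val_data`` are ``(grids, sides, labels)`` of
    standardized grids, integer side codes and integer labels.
    """
    config = config or TrainConfig()
    tg, ts, tl = (np.asarray(a) for a in train_data)
    vg, vs, vl = (np.asarray(a) for a in val_data)
    if len(tg) == 0 or len(vg) == 0:
        raise ValueError("empty training or validation set")
    weights = (class_weights(tl, model.config.n_classes)
               if config.weighted_loss
               else np.ones(model.config.n_classes))
    sample_w = None
    if config.balanced_sampling:
        inv = 1.0 / np.bincount(tl, minlength=model.config.n_classes)
        sample_w = inv[tl] / inv[tl].sum()

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.layers(), lr=config.learning_rate)
    history = TrainHistory()
    best_state = model.get_state()
    n_epoch = config.samples_per_epoch or len(tg)
    since_best = 0
    patience_ref = np.inf

    for epoch in range(config.max_epochs):
        idx = rng.choice(len(tg), size=n_epoch, replace=True, p=sample_w) \
            if sample_w is not None else rng.permutation(len(tg))[:n_epoch]
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, len(idx), config.batch_size):
            batch = idx[i:i + config.batch_size]
            logits = model.forward(tg[batch], ts[batch], training=True)
            loss, dlogits = nn.weighted_cross_entropy(logits, tl[batch],
                                                      weights)
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        val_loss = _evaluate_loss(model, vg, vs, vl, weights)
        history.train_loss.append(epoch_loss / max(n_batches, 1))
        history.val_loss.append(float(val_loss))
        if val_loss < history.best_val_loss:
            # checkpoint tracks the absolute minimum ...
            history.best_val_loss = float(val_loss)
            history.best_epoch = epoch
            best_state = model.get_state()
        if val_loss < patience_ref - config.min_delta:
            # ... while patience requires a material improvement
            patience_ref = float(val_loss)
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.set_state(best_state)
    return history


# ---------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------
def predict(model: PlantarCNN, grids: np.ndarray, sides: np.ndarray,
            fold_stats: tuple[float, float], batch: int = 32
            ) -> list[Prediction]:
    """Standardize with the fold statistics and run inference."""
    mean, sd = fold_stats
    x = (np.asarray(grids, dtype=np.float64) - mean) / sd
    sides = np.asarray(sides)
    out: list[Prediction] = []
    for i in range(0, len(x), batch):
        logits = model.forward(x[i:i + batch], sides[i:i + batch],
                               training=False)
        probs = nn.softmax(logits.astype(np.float64))
        for p in probs:
            lab = int(np.argmax(p))
            out.append(Prediction(probabilities=p, label=lab,
                                  is_outlier=lab != 0))
    return out


def dataset_arrays(ds: Dataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(grids, side codes, labels) arrays from a dataset."""
    sides = np.array([SIDE_INDEX[Side(s)] for s in ds.manifest["side"]])
    labels = ds.manifest["label"].astype(int).to_numpy()
    return ds.grids.astype(np.float64), sides, labels
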