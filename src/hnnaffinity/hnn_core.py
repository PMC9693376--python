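"""The hybrid neural network: CNNs over SMILES and pocket sequence plus
an MLP over interaction descriptors, merged into a linear regression head.

Architecture
------------
* CNN-1 (ligand branch): integer-encoded SMILES of length L -> embedding
  (95 tokens x 100) -> one or two Conv1D layers (kernel 3, ReLU, L2) ->
  global max pooling -> dropout.
* CNN-2 (pocket branch): integer-encoded sequence of length M ->
  embedding (21 tokens x 20) -> same conv/pool/dropout stack.
* FCNN (descriptor branch): width-D interaction-descriptor vector ->
  dense ReLU layers with dropout and L2.
* Branch outputs are concatenated, passed through one dense ReLU layer,
  and a single linear unit emits the predicted pK.

The three-branch configuration is the "denovo" variant; switching the
descriptor branch off gives the sequence+SMILES "affinity" variant.
Training minimises mean-squared error with Adam, early-stopping on a
held-out validation fraction of the training data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .featurize import EncodedBatch

logger = logging.getLogger(__name__)

ARTIFACT_VERSION = 1

SMILES_VOCAB_SIZE = 94
POCKET_VOCAB_SIZE = 20

FILTER_CHOICES = (128, 256, 512, 1024)
DROPOUT_CHOICES = (0.2, 0.3, 0.4, 0.5)
L2_CHOICES = (0.01, 0.001, 0.0001)
PADDING_CHOICES = ("valid", "same")
CONV_LAYER_CHOICES = (1, 2)


@dataclass
class HnnConfig:
    """Every architecture and training knob of the hybrid model."""

    use_smiles_branch: bool = True
    use_sequence_branch: bool = True
    use_descriptor_branch: bool = True
    L: int = 325
    M: int = 150
    D: int = 348
    smiles_embed_dim: int = 100
    seq_embed_dim: int = 20
    conv_filters: int = 128
    kernel_size: int = 3
    n_conv_layers: int = 1
    conv_padding: str = "valid"
    dropout_rate: float = 0.2
    l2_lambda: float = 0.001
    fcnn_hidden: list[int] = field(default_factory=lambda: [256, 128])
    merge_hidden: int = 128
    seed: int = 0
    # training
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    early_stopping_patience: int = 20
    val_fraction: float = 0.1

    def validate(self) -> None:
        if not (self.use_smiles_branch or self.use_sequence_branch
                or self.use_descriptor_branch):
            raise ValueError("at least one branch must be enabled")
        if self.conv_filters not in FILTER_CHOICES:
            raise ValueError(f"conv_filters must be one of {FILTER_CHOICES}")
        if self.dropout_rate not in DROPOUT_CHOICES:
            raise ValueError(f"dropout_rate must be one of {DROPOUT_CHOICES}")
        if self.l2_lambda not in L2_CHOICES:
            raise ValueError(f"l2_lambda must be one of {L2_CHOICES}")
        if self.conv_padding not in PADDING_CHOICES:
            raise ValueError(f"conv_padding must be one of {PADDING_CHOICES}")
        if self.n_conv_layers not in CONV_LAYER_CHOICES:
            raise ValueError(f"n_conv_layers must be one of {CONV_LAYER_CHOICES}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2_lambda <= 0:
            raise ValueError("l2_lambda must be positive")

    @property
    def enabled_inputs(self) -> tuple[str, ...]:
        names = []
        if self.use_smiles_branch:
            names.append("smiles")
        if self.use_sequence_branch:
            names.append("sequence")
        if self.use_descriptor_branch:
            names.append("descriptors")
        return tuple(names)


def denovo_config(**overrides) -> HnnConfig:
    """Three-branch configuration (sequence + SMILES + descriptors)."""
    return dataclasses.replace(HnnConfig(), **overrides)


def affinity_config(**overrides) -> HnnConfig:
    """Two-branch configuration (sequence + SMILES only)."""
    overrides.setdefault("use_descriptor_branch", False)
    return dataclasses.replace(HnnConfig(), **overrides)


class HnnModel:
    """An (initially untrained) hybrid network built from an HnnConfig."""

    def __init__(self, config: HnnConfig):
        config.validate()
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        c = config
        self.branches: dict[str, nn.Sequential] = {}
        if c.use_smiles_branch:
            self.branches["smiles"] = self._conv_branch(
                SMILES_VOCAB_SIZE + 1, c.smiles_embed_dim)
        if c.use_sequence_branch:
            self.branches["sequence"] = self._conv_branch(
                POCKET_VOCAB_SIZE + 1, c.seq_embed_dim)
        if c.use_descriptor_branch:
            layers: list[nn.Layer] = []
            width = c.D
            for h in c.fcnn_hidden:
                layers += [nn.Dense(width, h, c.l2_lambda, self.rng),
                           nn.ReLU(),
                           nn.Dropout(c.dropout_rate, self.rng)]
                width = h
            self.branches["descriptors"] = nn.Sequential(layers)
        merged_width = sum(self._branch_width(name) for name in self.branches)
        self.head = nn.Sequential([
            nn.Dense(merged_width, c.merge_hidden, c.l2_lambda, self.rng),
            nn.ReLU(),
            nn.Dense(c.merge_hidden, 1, c.l2_lambda, self.rng),
        ])
        self._layers = [l for b in self.branches.values() for l in b.layers]
        self._layers += self.head.layers

    def _conv_branch(self, vocab: int, embed_dim: int) -> nn.Sequential:
        c = self.config
        layers: list[nn.Layer] = [nn.Embedding(vocab, embed_dim, self.rng)]
        in_ch = embed_dim
        for _ in range(c.n_conv_layers):
            layers += [
                nn.Conv1D(in_ch, c.conv_filters, c.kernel_size,
                          c.conv_padding, c.l2_lambda, self.rng),
                nn.ReLU(),
            ]
            in_ch = c.conv_filters
        layers += [nn.GlobalMaxPool(), nn.Dropout(c.dropout_rate, self.rng)]
        return nn.Sequential(layers)

    def _branch_width(self, name: str) -> int:
        if name in ("smiles", "sequence"):
            return self.config.conv_filters
        return self.config.fcnn_hidden[-1] if self.config.fcnn_hidden else self.config.D

    # ------------------------------------------------------------------
    def _gather_inputs(self, batch) -> dict[str, np.ndarray]:
        c = self.config
        if isinstance(batch, EncodedBatch):
            inputs = {}
            if c.use_smiles_branch:
                inputs["smiles"] = batch.smiles_codes
            if c.use_sequence_branch:
                inputs["sequence"] = batch.pocket_codes
            if c.use_descriptor_branch:
                inputs["descriptors"] = batch.descriptors
        elif isinstance(batch, dict):
            extra = set(batch) - set(self.branches)
            if extra:
                raise ValueError(
                    f"inputs {sorted(extra)} supplied but those branches are "
                    f"disabled; enabled: {sorted(self.branches)}"
                )
            missing = set(self.branches) - set(batch)
            if missing:
                raise ValueError(f"missing inputs for branches {sorted(missing)}")
            inputs = dict(batch)
        else:
            raise TypeError("batch must be an EncodedBatch or a dict of arrays")
        expected = {"smiles": c.L, "sequence": c.M, "descriptors": c.D}
        K = None
        for name, arr in inputs.items():
            arr = np.asarray(arr)
            if arr.ndim != 2 or arr.shape[1] != expected[name]:
                raise ValueError(
                    f"{name} input has shape {arr.shape}, expected "
                    f"(K, {expected[name]})"
                )
            if K is None:
                K = arr.shape[0]
            elif arr.shape[0] != K:
                raise ValueError("branch inputs disagree on row count K")
            inputs[name] = arr
        if "descriptors" in inputs:
            inputs["descriptors"] = inputs["descriptors"].astype(
                np.float32, copy=False)
        return inputs

    def forward(self, inputs: dict[str, np.ndarray], train: bool = False) -> np.ndarray:
        outs = [self.branches[name].forward(inputs[name], train=train)
                for name in self.branches]
        self._split = [o.shape[1] for o in outs]
        merged = np.concatenate(outs, axis=1) if len(outs) > 1 else outs[0]
        return self.head.forward(merged, train=train)[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        grad = self.head.backward(dy[:, None])
        offsets = np.cumsum([0] + self._split)
        for (name, branch), lo, hi in zip(
            self.branches.items(), offsets[:-1], offsets[1:]
        ):
            branch.backward(grad[:, lo:hi])

    def reg_loss(self) -> float:
        return sum(l.reg_loss() for l in self._layers)

    def predict(self, batch, chunk: int = 256) -> np.ndarray:
        """Pure function of (weights, inputs); row-aligned with the batch."""
        inputs = self._gather_inputs(batch)
        K = next(iter(inputs.values())).shape[0]
        if K == 0:
            return np.zeros(0, dtype=np.float64)
        preds = []
        for lo in range(0, K, chunk):
            sub = {k: v[lo:lo + chunk] for k, v in inputs.items()}
            preds.append(self.forward(sub, train=False))
        return np.concatenate(preds).astype(np.float64)

    # -- weights as a flat ordered dict, for save/load and snapshots ----
    def get_weights(self) -> dict[str, np.ndarray]:
        return {
            f"{i}/{key}": layer.p[key].copy()
            for i, layer in enumerate(self._layers)
            for key in sorted(layer.p)
        }

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        expected = {
            f"{i}/{key}": layer.p[key].shape
            for i, layer in enumerate(self._layers)
            for key in sorted(layer.p)
        }
        if set(weights) != set(expected):
            raise ValueError("weight keys do not match the model architecture")
        for i, layer in enumerate(self._layers):
            for key in sorted(layer.p):
                arr = np.asarray(weights[f"{i}/{key}"], dtype=np.float32)
                if arr.shape != expected[f"{i}/{key}"]:
                    raise ValueError(f"weight {i}/{key} has wrong shape {arr.shape}")
                layer.p[key] = arr


@dataclass
class TrainedModel:
    """A fitted hybrid model plus its training history and provenance."""

    model: HnnModel
    config: HnnConfig
    history: dict[str, list[float]]
    provenance: dict


def build_model(config: HnnConfig | None = None) -> HnnModel:
    return HnnModel(config or HnnConfig())


def train_model(
    model: HnnModel,
    batch,
    labels: np.ndarray,
    verbose: bool = False,
) -> TrainedModel:
    """Fit the model with Adam on MSE; deterministic given config.seed.

    A ``val_fraction`` slice of the (seed-shuffled) training data is
    held out for early stopping; the weights of the best validation
    epoch are restored.
    """
    c = model.config
    inputs = model._gather_inputs(batch)
    y = np.asarray(labels, dtype=np.float32)
    K = next(iter(inputs.values())).shape[0]
    if y.shape != (K,):
        raise ValueError(f"labels shape {y.shape} does not match K={K}")
    if not np.all(np.isfinite(y)):
        raise ValueError("labels contain non-finite values")
    if K < 2:
        raise ValueError("need at least 2 training samples")
    batch_size = c.batch_size
    if K < batch_size:
        warnings.warn(f"batch_size {batch_size} clamped to dataset size {K}")
        batch_size = K

    rng = model.rng
    order = rng.permutation(K)
    n_val = int(round(c.val_fraction * K)) if c.val_fraction > 0 else 0
    val_idx, train_idx = order[:n_val], order[n_val:]
    tr = {k: v[train_idx] for k, v in inputs.items()}
    va = {k: v[val_idx] for k, v in inputs.items()}
    y_tr, y_va = y[train_idx], y[val_idx]
    n_tr = len(train_idx)

    optimiser = nn.Adam(nn.collect_params(model._layers), lr=c.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val, best_weights, patience_left = np.inf, None, c.early_stopping_patience
    for epoch in range(c.max_epochs):
        perm = rng.permutation(n_tr)
        epoch_loss = 0.0
        for lo in range(0, n_tr, batch_size):
            idx = perm[lo:lo + batch_size]
            xb = {k: v[idx] for k, v in tr.items()}
            yb = y_tr[idx]
            pred = model.forward(xb, train=True)
            resid = pred - yb
            epoch_loss += float(np.sum(resid ** 2))
            model.backward((2.0 / len(idx)) * resid)
            optimiser.step()
        train_mse = epoch_loss / n_tr
        history["train_loss"].append(train_mse)
        if n_val:
            val_pred = _predict_inputs(model, va)
            val_mse = float(np.mean((val_pred - y_va) ** 2))
            history["val_loss"].append(val_mse)
            if val_mse < best_val - 1e-7:
                best_val, best_weights = val_mse, model.get_weights()
                patience_left = c.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    if verbose:
                        logger.info("early stop at epoch %d", epoch + 1)
                    break
        if verbose:
            logger.info("epoch %d train_mse %.4f val_mse %s", epoch + 1,
                        train_mse, history["val_loss"][-1] if n_val else "n/a")
    if best_weights is not None:
        model.set_weights(best_weights)
    provenance = {
        "seed": c.seed,
        "n_train": int(n_tr),
        "n_val": int(n_val),
        "epochs_run": len(history["train_loss"]),
        "artifact_version": ARTIFACT_VERSION,
    }
    return TrainedModel(model=model, config=c, history=history,
                        provenance=provenance)


def _predict_inputs(model: HnnModel, inputs: dict[str, np.ndarray],
                    chunk: int = 256) -> np.ndarray:
    K = next(iter(inputs.values())).shape[0]
    preds = []
    for lo in range(0, K, chunk):
        preds.append(model.forward(
            {k: v[lo:lo + chunk] for k, v in inputs.items()}, train=False))
    return np.concatenate(preds) if preds else np.zeros(0, dtype=np.float32)


def predict(trained: TrainedModel | HnnModel, batch) -> np.ndarray:
    model = trained.model if isinstance(trained, TrainedModel) else trained
    return model.predict(batch)


def save_model(trained: TrainedModel, path: str | Path) -> None:
    """Persist a trained model as a directory of JSON + npz weights."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(trained.config)
    (path / "config.json").write_text(json.dumps(cfg, indent=1))
    meta = {
        "artifact_version": ARTIFACT_VERSION,
        "history": trained.history,
        "provenance": trained.provenance,
    }
    (path / "provenance.json").write_text(json.dumps(meta, indent=1))
    np.savez(path / "weights.npz", **trained.model.get_weights())


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    try:
        cfg_dict = json.loads((path / "config.json").read_text())
        meta = json.loads((path / "provenance.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"unreadable model artifact at {path}: {exc}") from exc
    version = meta.get("artifact_version")
    if version != ARTIFACT_VERSION:
        raise ValueError(
            f"model artifact version {version!r} unsupported "
            f"(expected {ARTIFACT_VERSION})"
        )
    config = HnnConfig(**cfg_dict)
    model = HnnModel(config)
    try:
        with np.load(path / "weights.npz") as npz:
            model.set_weights({k: npz[k] for k in npz.files})
    except Exception as exc:
        raise ValueError(f"corrupt weights in {path}: {exc}") from exc
    return TrainedModel(model=model, config=config,
                        history=meta.get("history", {}),
                        provenance=meta.get("provenance", {}))
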