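"""Twin 1D-CNN regression of normalized drug response.

Two convolutional branches distil features independently: the drug branch
consumes the one-hot SMILES grid with each vocabulary row as an input
channel (so convolution slides along the string within one chemical
symbol), and the cell branch consumes the binary genomic feature vector as
a single channel.  Each branch stacks three identical layers — convolution
of width 7 and stride 1 with length-preserving (same) padding, ReLU, then
max pooling of width 3 and stride 3 with ceiling semantics — with 40, 80
and 60 output channels respectively.  Under these defaults the flattened
branch outputs are 420-dimensional for a length-188 drug grid and
1680-dimensional for a 735-feature cell vector.

The flattened branch outputs are concatenated and regressed through three
1024-unit hidden layers with ReLU and dropout 0.5, ending in a single
logistic output matching the (0, 1) range of normalized IC50.  Training
minimizes mean squared error with Adam and stops early once validation
RMSE has not improved for a configurable number of epochs, restoring the
best-validation parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn
from .gdsc_io import InteractionTable
from .smiles_onehot import EncoderConfig, encode
from .splits import SplitSpec

__all__ = [
    "BranchConfig", "HeadConfig", "TrainConfig", "branch_output_dim",
    "TwinCNN", "build_model", "TableTensors", "prepare_tensors",
    "TrainingHistory", "train", "predict", "embed_drugs", "embed_cells",
    "save_model", "load_model",
]


@dataclass(frozen=True)
class BranchConfig:
    """Layer stack of one convolutional branch."""

    conv_widths: tuple[int, ...] = (7, 7, 7)
    conv_strides: tuple[int, ...] = (1, 1, 1)
    channels: tuple[int, ...] = (40, 80, 60)
    pool_widths: tuple[int, ...] = (3, 3, 3)
    pool_strides: tuple[int, ...] = (3, 3, 3)
    padding_mode: str = "same"

    def __post_init__(self) -> None:
        lengths = {len(self.conv_widths), len(self.conv_strides),
                   len(self.channels), len(self.pool_widths),
                   len(self.pool_strides)}
        if len(lengths) != 1:
            raise ValueError("branch config lists must have equal length")
        if self.padding_mode not in ("same", "valid"):
            raise ValueError(f"unknown padding mode {self.padding_mode!r}")
        for v in (*self.conv_widths, *self.conv_strides,
                  *self.pool_widths, *self.pool_strides, *self.channels):
            if v < 1:
                raise ValueError("widths, strides and channels must be positive")


@dataclass(frozen=True)
class HeadConfig:
    """Fully connected regression head; output activation is logistic."""

    hidden_sizes: tuple[int, ...] = (1024, 1024, 1024)
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    ``warmup_steps`` linearly ramps the learning rate from zero over the
    first optimizer steps.  Early Adam steps move every weight by roughly
    the full learning rate regardless of gradient magnitude, which at
    aggressive rates can slam the logistic output into saturation where
    the squared-error gradient vanishes and training dies; a short warmup
    removes that failure mode.
    """

    patience_epochs: int = 10
    max_epochs: int = 500
    batch_size: int = 128
    learning_rate: float = 1e-4
    seed: int = 0
    optimizer_name: str = "adam"
    warmup_steps: int = 0

    def __post_init__(self) -> None:
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")
        if self.warmup_steps < 0:
            raise ValueError("warmup_steps must be >= 0")
        if self.optimizer_name != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer_name!r}")


def branch_output_dim(input_len: int, cfg: BranchConfig = BranchConfig()) -> int:
    """Flattened width of one branch's output for a given input length.

    Walks the layer stack: each convolution maps the length under the
    configured padding mode, each pooling divides it (ceiling division for
    same-style pooling); the final length times the last channel count is
    the flattened dimension.
    """
    if input_len < 1:
        raise ValueError("input_len must be positive")
    length = input_len
    for cw, cs, pw, ps in zip(cfg.conv_widths, cfg.conv_strides,
                              cfg.pool_widths, cfg.pool_strides):
        length = _nn.conv_output_len(length, cw, cs, cfg.padding_mode)
        length = _nn.pool_output_len(length, pw, ps, cfg.padding_mode)
    return length * cfg.channels[-1]


class _Branch:
    def __init__(self, in_channels: int, cfg: BranchConfig,
                 rng: np.random.Generator, dtype):
        self.layers: list[_nn.Layer] = []
        c_in = in_channels
        for cw, cs, ch, pw, ps in zip(cfg.conv_widths, cfg.conv_strides,
                                      cfg.channels, cfg.pool_widths,
                                      cfg.pool_strides):
            self.layers.append(_nn.Conv1D(c_in, ch, cw, cs, cfg.padding_mode,
                                          rng, dtype))
            self.layers.append(_nn.ReLU())
            self.layers.append(_nn.MaxPool1D(pw, ps, cfg.padding_mode))
            c_in = ch
        self.flatten = _nn.Flatten()

    def forward(self, x, *, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return self.flatten.forward(x)

    def backward(self, dout):
        dout = self.flatten.backward(dout)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self) -> list[_nn.Param]:
        return [p for layer in self.layers for p in layer.params]


class TwinCNN:
    """The twin-branch convolutional regression network.

    Maps a batch of (one-hot drug grid, cell feature vector) pairs to
    predictions in (0, 1).  Construction is fully determined by the configs
    and the seed; two models built with the same arguments make identical
    predictions.
    """

    def __init__(self, vocab_size: int, max_len: int, n_cell_features: int,
                 drug_cfg: BranchConfig = BranchConfig(),
                 cell_cfg: BranchConfig = BranchConfig(),
                 head_cfg: HeadConfig = HeadConfig(),
                 seed: int = 0, dtype=np.float32):
        if min(vocab_size, max_len, n_cell_features) < 1:
            raise ValueError("model dimensions must be positive")
        rng = np.random.default_rng(seed)
        self.vocab_size, self.max_len = vocab_size, max_len
        self.n_cell_features = n_cell_features
        self.drug_cfg, self.cell_cfg, self.head_cfg = drug_cfg, cell_cfg, head_cfg
        self.seed, self.dtype = seed, dtype

        self.drug_branch = _Branch(vocab_size, drug_cfg, rng, dtype)
        self.cell_branch = _Branch(1, cell_cfg, rng, dtype)
        self.drug_dim = branch_output_dim(max_len, drug_cfg)
        self.cell_dim = branch_output_dim(n_cell_features, cell_cfg)

        self.head: list[_nn.Layer] = []
        d_in = self.drug_dim + self.cell_dim
        for h in head_cfg.hidden_sizes:
            self.head.append(_nn.Dense(d_in, h, rng, dtype))
            self.head.append(_nn.ReLU())
            self.head.append(_nn.Dropout(head_cfg.dropout))
            d_in = h
        self.head.append(_nn.Dense(d_in, 1, rng, dtype))
        self.head.append(_nn.Sigmoid())

    @property
    def params(self) -> list[_nn.Param]:
        return (self.drug_branch.params + self.cell_branch.params
                + [p for layer in self.head for p in layer.params])

    def forward(self, drug_x: np.ndarray, cell_x: np.ndarray, *,
                train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if drug_x.shape[1:] != (self.vocab_size, self.max_len):
            raise ValueError(f"drug input shape {drug_x.shape[1:]} incompatible "
                             f"with ({self.vocab_size}, {self.max_len})")
        if cell_x.shape[1:] != (1, self.n_cell_features):
            raise ValueError(f"cell input shape {cell_x.shape[1:]} incompatible "
                             f"with (1, {self.n_cell_features})")
        zd = self.drug_branch.forward(drug_x.astype(self.dtype, copy=False),
                                      train=train, rng=rng)
        zc = self.cell_branch.forward(cell_x.astype(self.dtype, copy=False),
                                      train=train, rng=rng)
        h = np.concatenate([zd, zc], axis=1)
        for layer in self.head:
            h = layer.forward(h, train=train, rng=rng)
        return h[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        dout = dpred[:, None].astype(self.dtype, copy=False)
        for layer in reversed(self.head):
            dout = layer.backward(dout)
        self.drug_branch.backward(dout[:, :self.drug_dim])
        self.cell_branch.backward(dout[:, self.drug_dim:])

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params, state):
            p.value[...] = v


def build_model(vocab_size: int, max_len: int, n_cell_features: int,
                drug_cfg: BranchConfig = BranchConfig(),
                cell_cfg: BranchConfig = BranchConfig(),
                head_cfg: HeadConfig = HeadConfig(),
                seed: int = 0) -> TwinCNN:
    return TwinCNN(vocab_size, max_len, n_cell_features,
                   drug_cfg, cell_cfg, head_cfg, seed=seed)


@dataclass
class TableTensors:
    """Model-ready arrays for one interaction table.

    ``drug_onehots[i]`` is the encoded grid of ``drug_ids[i]``;
    ``cell_features[j]`` the (1, n_features) vector of ``cell_ids[j]``.
    """

    drug_ids: list[str]
    cell_ids: list[str]
    drug_onehots: np.ndarray   # (n_drugs, vocab, max_len)
    cell_features: np.ndarray  # (n_cells, 1, n_features)
    values: np.ndarray         # (n_drugs, n_cells) normalized IC50
    known_mask: np.ndarray
    encoder: EncoderConfig
    _drug_index: dict[str, int] = field(init=False, repr=False)
    _cell_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._drug_index = {d: i for i, d in enumerate(self.drug_ids)}
        self._cell_index = {c: j for j, c in enumerate(self.cell_ids)}

    def pair_arrays(self, pairs: Sequence[tuple[str, str]]
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Row/column index vectors and labels for a list of pairs."""
        try:
            di = np.array([self._drug_index[d] for d, _ in pairs], dtype=np.intp)
            ci = np.array([self._cell_index[c] for _, c in pairs], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown entity {exc.args[0]!r}") from None
        return di, ci, self.values[di, ci]


def prepare_tensors(table: InteractionTable,
                    encoder: EncoderConfig | None = None) -> TableTensors:
    """Encode all drugs and stack cell features for training and inference.

    The encoder (vocabulary and grid width) is derived from the table's own
    SMILES corpus unless one is supplied, so neither the vocabulary size nor
    the maximum length is ever hard-coded.
    """
    corpus = [d.canonical_smiles for d in table.drugs]
    if encoder is None:
        encoder = EncoderConfig.from_corpus(corpus)
    stack = np.stack([
        encode(d.canonical_smiles, encoder, drug_id=d.drug_id).matrix
        for d in table.drugs
    ]).astype(np.float32)
    cells = np.stack([c.features for c in table.cells])[:, None, :].astype(
        np.float32)
    return TableTensors(
        drug_ids=table.drug_ids, cell_ids=table.cell_ids,
        drug_onehots=stack, cell_features=cells,
        values=table.values, known_mask=table.known_mask, encoder=encoder,
    )


@dataclass
class TrainingHistory:
    train_rmse: list[float]
    val_rmse: list[float]
    best_epoch: int  # 0-based

    @property
    def best_val_rmse(self) -> float:
        return self.val_rmse[self.best_epoch]

    def to_csv(self) -> str:
        lines = ["epoch,train_rmse,val_rmse"]
        for e, (tr, va) in enumerate(zip(self.train_rmse, self.val_rmse)):
            lines.append(f"{e},{tr:.8f},{va:.8f}")
        return "\n".join(lines) + "\n"


def _batched_forward(model: TwinCNN, tensors: TableTensors,
                     di: np.ndarray, ci: np.ndarray,
                     batch_size: int = 512) -> np.ndarray:
    out = np.empty(len(di))
    for s in range(0, len(di), batch_size):
        sl = slice(s, s + batch_size)
        out[sl] = model.forward(tensors.drug_onehots[di[sl]],
                                tensors.cell_features[ci[sl]])
    return out


def train(model: TwinCNN, tensors: TableTensors, split: SplitSpec,
          cfg: TrainConfig = TrainConfig()) -> TrainingHistory:
    """Fit with minibatch Adam on MSE; early-stop on validation RMSE.

    Training stops when validation RMSE has not improved for
    ``cfg.patience_epochs`` consecutive epochs (or at ``cfg.max_epochs``);
    the parameters from the best-validation epoch are restored before
    returning.
    """
    if not split.train_pairs or not split.val_pairs:
        raise ValueError("training and validation sets must be non-empty")
    tr_d, tr_c, tr_y = tensors.pair_arrays(split.train_pairs)
    va_d, va_c, va_y = tensors.pair_arrays(split.val_pairs)

    opt = _nn.Adam(model.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    best_state = model.get_state()
    best_val = np.inf
    best_epoch = -1
    history = TrainingHistory(train_rmse=[], val_rmse=[], best_epoch=0)

    n = len(tr_y)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        sq_err = 0.0
        for s in range(0, n, cfg.batch_size):
            if cfg.warmup_steps:
                opt.lr = cfg.learning_rate * min(
                    1.0, (opt.t + 1) / cfg.warmup_steps)
            idx = order[s:s + cfg.batch_size]
            xb_d = tensors.drug_onehots[tr_d[idx]]
            xb_c = tensors.cell_features[tr_c[idx]]
            yb = tr_y[idx]
            pred = model.forward(xb_d, xb_c, train=True, rng=rng)
            err = pred - yb
            sq_err += float(err @ err)
            opt.zero_grad()
            model.backward(2.0 * err / len(idx))
            opt.step()
        history.train_rmse.append(float(np.sqrt(sq_err / n)))

        val_pred = _batched_forward(model, tensors, va_d, va_c)
        val_rmse = float(np.sqrt(np.mean((val_pred - va_y) ** 2)))
        history.val_rmse.append(val_rmse)
        if val_rmse < best_val:
            best_val = val_rmse
            best_epoch = epoch
            best_state = model.get_state()
        elif epoch - best_epoch >= cfg.patience_epochs:
            break
    model.set_state(best_state)
    history.best_epoch = best_epoch
    return history


def predict(model: TwinCNN, tensors: TableTensors,
            pairs: Sequence[tuple[str, str]],
            batch_size: int = 512) -> np.ndarray:
    """Deterministic inference (dropout disabled) for a list of pairs."""
    di = np.array([tensors._drug_index.get(d, -1) for d, _ in pairs])
    ci = np.array([tensors._cell_index.get(c, -1) for _, c in pairs])
    if (di < 0).any() or (ci < 0).any():
        k = int(np.argmax((di < 0) | (ci < 0)))
        raise KeyError(f"unknown drug or cell line in pair {pairs[k]}")
    return _batched_forward(model, tensors, di.astype(np.intp),
                            ci.astype(np.intp), batch_size)


def embed_drugs(model: TwinCNN, drug_onehots: np.ndarray,
                batch_size: int = 512) -> np.ndarray:
    """Flattened last-convolution-layer activations, one row per drug."""
    out = np.empty((len(drug_onehots), model.drug_dim), dtype=model.dtype)
    for s in range(0, len(drug_onehots), batch_size):
        sl = slice(s, s + batch_size)
        out[sl] = model.drug_branch.forward(
            drug_onehots[sl].astype(model.dtype, copy=False))
    return out


def embed_cells(model: TwinCNN, cell_features: np.ndarray,
                batch_size: int = 512) -> np.ndarray:
    """Flattened last-convolution-layer activations, one row per cell line."""
    out = np.empty((len(cell_features), model.cell_dim), dtype=model.dtype)
    for s in range(0, len(cell_features), batch_size):
        sl = slice(s, s + batch_size)
        out[sl] = model.cell_branch.forward(
            cell_features[sl].astype(model.dtype, copy=False))
    return out


def save_model(model: TwinCNN, out_dir: str | Path,
               history: TrainingHistory | None = None) -> Path:
    """Checkpoint: parameter arrays plus a JSON manifest of the configs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "params.npz",
             **{f"p{i}": p.value for i, p in enumerate(model.params)})
    manifest = {
        "vocab_size": model.vocab_size, "max_len": model.max_len,
        "n_cell_features": model.n_cell_features, "seed": model.seed,
        "drug_cfg": model.drug_cfg.__dict__, "cell_cfg": model.cell_cfg.__dict__,
        "head_cfg": model.head_cfg.__dict__,
    }
    (out / "model.json").write_text(json.dumps(manifest, indent=1))
    if history is not None:
        (out / "history.csv").write_text(history.to_csv())
    return out


def load_model(in_dir: str | Path) -> TwinCNN:
    in_dir = Path(in_dir)
    m = json.loads((in_dir / "model.json").read_text())

    def _tuplify(d):
        return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}

    model = TwinCNN(
        m["vocab_size"], m["max_len"], m["n_cell_features"],
        drug_cfg=BranchConfig(**_tuplify(m["drug_cfg"])),
        cell_cfg=BranchConfig(**_tuplify(m["cell_cfg"])),
        head_cfg=HeadConfig(**_tuplify(m["head_cfg"])),
        seed=m["seed"],
    )
    with np.load(in_dir / "params.npz") as data:
        model.set_state([data[f"p{i}"] for i in range(len(model.params))])
    return model
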