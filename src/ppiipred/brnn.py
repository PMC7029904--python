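"""Bidirectional recurrent sequence labeller.

Per-position output o_j = N_O(i_j, hF_j, hB_j) with hidden chains
hF_j = N_F(i_j, hF_{j-1}) (left to right) and hB_j = N_B(i_j, hB_{j+1})
(right to left), boundary states zero.  Each of the three update
functions is a two-layer feed-forward network (tanh hidden layer; the
output unit is a sigmoid).  Training is plain stochastic gradient
descent with mean binary cross-entropy loss, a fixed number of weight
updates per epoch, and a learning rate halved when the validation error
stalls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import ALPHABET, FeatureMatrix

_PARAM_NAMES = (
    "Wf1x", "Wf1h", "bf1", "Wf2", "bf2",
    "Wb1x", "Wb1h", "bb1", "Wb2", "bb2",
    "Wo1x", "Wo1f", "Wo1b", "bo1", "Wo2", "bo2",
)


@dataclass
class TrainConfig:
    epochs: int = 2000
    updates_per_epoch: int = 1920
    lr_init: float = 0.005
    lr_halving_patience: int = 1000
    hidden_dim: int = 11
    mlp_hidden: int = 11
    seed: int = 0

    def __post_init__(self):
        for name in ("epochs", "updates_per_epoch", "lr_halving_patience",
                     "hidden_dim", "mlp_hidden"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lr_init <= 0:
            raise ValueError("lr_init must be positive")


@dataclass
class BRNNModel:
    input_dim: int
    hidden_dim: int
    mlp_hidden: int
    seed: int
    params: dict[str, np.ndarray] = field(default_factory=dict)

    def copy(self) -> "BRNNModel":
        return BRNNModel(self.input_dim, self.hidden_dim, self.mlp_hidden,
                         self.seed, {k: v.copy() for k, v in self.params.items()})


def init_model(input_dim: int, hidden_dim: int = 11, mlp_hidden: int = 11,
               seed: int = 0) -> BRNNModel:
    """Seeded initialization: uniform weights scaled by 1/sqrt(fan_in)."""
    if min(input_dim, hidden_dim, mlp_hidden) <= 0:
        raise ValueError("all dimensions must be positive")
    rng = np.random.default_rng(seed)
    d, m, q = input_dim, hidden_dim, mlp_hidden

    def w(rows, cols, fan_in):
        return rng.uniform(-1.0, 1.0, size=(rows, cols)) / np.sqrt(fan_in)

    params = {
        "Wf1x": w(q, d, d + m), "Wf1h": w(q, m, d + m), "bf1": np.zeros(q),
        "Wf2": w(m, q, q), "bf2": np.zeros(m),
        "Wb1x": w(q, d, d + m), "Wb1h": w(q, m, d + m), "bb1": np.zeros(q),
        "Wb2": w(m, q, q), "bb2": np.zeros(m),
        "Wo1x": w(q, d, d + 2 * m), "Wo1f": w(q, m, d + 2 * m),
        "Wo1b": w(q, m, d + 2 * m), "bo1": np.zeros(q),
        "Wo2": w(1, q, q)[0], "bo2": np.zeros(1),
    }
    return BRNNModel(input_dim, hidden_dim, mlp_hidden, seed, params)


def _as_array(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.rows
    return np.asarray(features, float)


def _forward_pass(model: BRNNModel, x: np.ndarray):
    """Run both hidden chains and the output net; returns intermediates."""
    p = model.params
    n = x.shape[0]
    m = model.hidden_dim
    hf = np.zeros((n + 1, m))          # hf[j] = hF_j, hf[0] = 0
    hb = np.zeros((n + 2, m))          # hb[j] = hB_j, hb[n+1] = 0
    zf = np.empty((n, model.mlp_hidden))
    zb = np.empty((n, model.mlp_hidden))
    xf = x @ p["Wf1x"].T + p["bf1"]
    xb = x @ p["Wb1x"].T + p["bb1"]
    w1h_f, w2f, b2f = p["Wf1h"], p["Wf2"], p["bf2"]
    for j in range(1, n + 1):
        z = np.tanh(xf[j - 1] + w1h_f @ hf[j - 1])
        zf[j - 1] = z
        hf[j] = np.tanh(w2f @ z + b2f)
    w1h_b, w2b, b2b = p["Wb1h"], p["Wb2"], p["bb2"]
    for j in range(n, 0, -1):
        z = np.tanh(xb[j - 1] + w1h_b @ hb[j + 1])
        zb[j - 1] = z
        hb[j] = np.tanh(w2b @ z + b2b)
    hfm = hf[1:]
    hbm = hb[1:n + 1]
    zo = np.tanh(x @ p["Wo1x"].T + hfm @ p["Wo1f"].T + hbm @ p["Wo1b"].T + p["bo1"])
    logits = zo @ p["Wo2"] + p["bo2"][0]
    out = 1.0 / (1.0 + np.exp(-logits))
    return out, (x, hf, hb, zf, zb, zo)


def forward(model: BRNNModel, features) -> np.ndarray:
    """Per-residue scores in (0, 1), one per input row."""
    x = _as_array(features)
    if x.shape[1] != model.input_dim:
        raise ValueError(
            f"feature width {x.shape[1]} != model input_dim {model.input_dim}")
    out, _ = _forward_pass(model, x)
    return out


def loss(scores, labels) -> float:
    """Mean binary cross-entropy over residues."""
    s = np.clip(np.asarray(scores, float), 1e-12, 1 - 1e-12)
    y = np.asarray(labels, float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    return float(-np.mean(y * np.log(s) + (1 - y) * np.log(1 - s)))


def gradients(model: BRNNModel, features, labels):
    """Exact gradients of the mean-BCE loss for one sequence.

    Returns ``(loss_value, grads)`` with ``grads`` keyed like
    ``model.params``.
    """
    x = _as_array(features)
    y = np.asarray(labels, float)
    if x.shape[1] != model.input_dim:
        raise ValueError("feature width mismatch")
    out, (x, hf, hb, zf, zb, zo) = _forward_pass(model, x)
    p = model.params
    n = x.shape[0]
    lval = loss(out, y)

    dlogit = (out - y) / n                              # (n,)
    g = {}
    g["Wo2"] = zo.T @ dlogit
    g["bo2"] = np.array([dlogit.sum()])
    dzo = np.outer(dlogit, p["Wo2"]) * (1.0 - zo ** 2)  # (n, q)
    hfm = hf[1:]
    hbm = hb[1:n + 1]
    g["Wo1x"] = dzo.T @ x
    g["Wo1f"] = dzo.T @ hfm
    g["Wo1b"] = dzo.T @ hbm
    g["bo1"] = dzo.sum(axis=0)
    dhf = dzo @ p["Wo1f"]                               # (n, m)
    dhb = dzo @ p["Wo1b"]

    # forward chain: gradient flows j -> j-1
    d1f = np.empty_like(zf)
    d2f = np.empty((n, model.hidden_dim))
    w2f, w1h_f = p["Wf2"], p["Wf1h"]
    carry = np.zeros(model.hidden_dim)
    for j in range(n, 0, -1):
        dh = dhf[j - 1] + carry
        dp2 = dh * (1.0 - hf[j] ** 2)
        d2f[j - 1] = dp2
        da1 = (w2f.T @ dp2) * (1.0 - zf[j - 1] ** 2)
        d1f[j - 1] = da1
        carry = w1h_f.T @ da1
    g["Wf2"] = d2f.T @ zf
    g["bf2"] = d2f.sum(axis=0)
    g["Wf1x"] = d1f.T @ x
    g["Wf1h"] = d1f.T @ hf[:n]
    g["bf1"] = d1f.sum(axis=0)

    # backward chain: gradient flows j -> j+1
    d1b = np.empty_like(zb)
    d2b = np.empty((n, model.hidden_dim))
    w2b, w1h_b = p["Wb2"], p["Wb1h"]
    carry = np.zeros(model.hidden_dim)
    for j in range(1, n + 1):
        dh = dhb[j - 1] + carry
        dp2 = dh * (1.0 - hb[j] ** 2)
        d2b[j - 1] = dp2
        da1 = (w2b.T @ dp2) * (1.0 - zb[j - 1] ** 2)
        d1b[j - 1] = da1
        carry = w1h_b.T @ da1
    g["Wb2"] = d2b.T @ zb
    g["bb2"] = d2b.sum(axis=0)
    g["Wb1x"] = d1b.T @ x
    # hb[j+1] pairs with row j-1 of d1b
    g["Wb1h"] = d1b.T @ hb[2:n + 2]
    g["bb1"] = d1b.sum(axis=0)
    return lval, g


def batch_gradients(model: BRNNModel, batch: Sequence[tuple]):
    """Summed loss and gradients over (features, labels) pairs."""
    total = 0.0
    acc = None
    for feats, labels in batch:
        lval, g = gradients(model, feats, labels)
        total += lval
        if acc is None:
            acc = g
        else:
            for k in acc:
                acc[k] += g[k]
    return total, acc


def _validation_error(model: BRNNModel, valset, threshold: float = 0.5) -> float:
    """Fraction of residues misclassified at the threshold."""
    wrong = 0
    total = 0
    for feats, labels in valset:
        s = forward(model, feats)
        y = np.asarray(labels)
        wrong += int(np.sum((s >= threshold).astype(int) != y))
        total += len(y)
    return wrong / total if total else 0.0


def train(model: BRNNModel, dataset: Sequence[tuple], config: TrainConfig,
          validation: Optional[Sequence[tuple]] = None,
          verbose: bool = False):
    """SGD training loop.

    Each epoch the dataset is shuffled (seeded) and split into
    ``min(updates_per_epoch, len(dataset))`` groups; one averaged
    gradient step is taken per group.  The learning rate is halved
    whenever the validation error has not improved for
    ``lr_halving_patience`` consecutive epochs.  Returns
    ``(model, history)`` where history rows are dicts with epoch, loss,
    val_error and lr.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    model = model.copy()
    rng = np.random.default_rng(config.seed)
    n_groups = min(config.updates_per_epoch, len(dataset))
    lr = config.lr_init
    best_val = np.inf
    stall = 0
    history = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(dataset))
        groups = np.array_split(order, n_groups)
        epoch_loss = 0.0
        for grp in groups:
            batch = [dataset[i] for i in grp]
            lsum, g = batch_gradients(model, batch)
            epoch_loss += lsum
            scale = lr / len(batch)
            for k, v in g.items():
                model.params[k] -= scale * v
        epoch_loss /= len(dataset)
        if validation is not None:
            val_err = _validation_error(model, validation)
        else:
            val_err = _validation_error(model, dataset)
        if val_err < best_val - 1e-12:
            best_val = val_err
            stall = 0
        else:
            stall += 1
            if stall >= config.lr_halving_patience:
                lr *= 0.5
                stall = 0
        history.append({"epoch": epoch, "loss": epoch_loss,
                        "val_error": val_err, "lr": lr})
        if verbose and epoch % 50 == 0:
            print(f"epoch {epoch}: loss {epoch_loss:.4f} "
                  f"val_err {val_err:.4f} lr {lr:.2e}")
    return model, history


def ensemble_predict(models: Sequence[BRNNModel], features) -> np.ndarray:
    """Arithmetic mean of per-model score tracks."""
    if not models:
        raise ValueError("empty model list")
    dims = {m.input_dim for m in models}
    if len(dims) != 1:
        raise ValueError("models disagree on input_dim")
    return np.mean([forward(m, features) for m in models], axis=0)


# ---------------------------------------------------------------------------
# Serialization: a single JSON document — header plus array payload.

_FORMAT = "ppiipred-brnn-1"


def save_model(model: BRNNModel, path) -> None:
    doc = {
        "format": _FORMAT,
        "alphabet": ALPHABET,
        "layout": "[onehot20|length|charge|(profile20|gap)|iupred|espritz]",
        "input_dim": model.input_dim,
        "hidden_dim": model.hidden_dim,
        "mlp_hidden": model.mlp_hidden,
        "seed": model.seed,
        "params": {k: model.params[k].tolist() for k in _PARAM_NAMES},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> BRNNModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != _FORMAT:
        raise ValueError(f"{path}: unknown model format {doc.get('format')!r}")
    if doc.get("alphabet") != ALPHABET:
        raise ValueError(f"{path}: alphabet mismatch, refusing to load")
    params = {k: np.asarray(doc["params"][k], float) for k in _PARAM_NAMES}
    return BRNNModel(doc["input_dim"], doc["hidden_dim"], doc["mlp_hidden"],
                     doc["seed"], params)


def write_history_tsv(history: Sequence[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\tloss\tval_error\tlr\n")
        for row in history:
            fh.write(f"{row['epoch']}\t{row['loss']:.6f}\t"
                     f"{row['val_error']:.6f}\t{row['lr']:.6g}\n")
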