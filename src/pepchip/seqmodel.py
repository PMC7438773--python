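"""Recurrent sequence model: a GRU regressor over whole peptides.

An alternative to the binding-core network that reads the peptide
left-to-right through a gated recurrent unit and regresses the normalized
intensity from the final hidden state — no window max, the alignment is
implicit in the recurrence.  Implemented directly in NumPy with
backpropagation through time and Adam, sized to train on one CPU at
reduced scale.  Architectural details (hidden size, learning rate) are
configuration, not doctrine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import ENCODINGS, encode_matrix
from .arrays import ArrayDataset
from .partition import Partition


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def sequence_features(peptides: list[str], encoding: str = "blosum") -> np.ndarray:
    """Per-residue features: (n, length, 20) float32."""
    table = ENCODINGS[encoding].astype(np.float32)
    return table[encode_matrix(peptides)]


@dataclass
class SeqTrainConfig:
    hidden_size: int = 16
    n_restarts: int = 2
    learning_rate: float = 0.01
    batch_size: int = 64
    max_epochs: int = 120
    patience: int = 10
    encoding: str = "blosum"
    init_scale: float = 0.15


class GRUNetwork:
    """Single-layer GRU with a sigmoid readout from the final hidden state."""

    PARAM_NAMES = ("wz", "uz", "bz", "wr", "ur", "br", "wh", "uh", "bh", "v", "c")

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 init_scale: float = 0.15):
        s = init_scale
        self.hidden = hidden
        self.params = {
            "wz": rng.normal(0, s, (d_in, hidden)),
            "uz": rng.normal(0, s, (hidden, hidden)),
            "bz": np.zeros(hidden),
            "wr": rng.normal(0, s, (d_in, hidden)),
            "ur": rng.normal(0, s, (hidden, hidden)),
            "br": np.zeros(hidden),
            "wh": rng.normal(0, s, (d_in, hidden)),
            "uh": rng.normal(0, s, (hidden, hidden)),
            "bh": np.zeros(hidden),
            "v": rng.normal(0, s, hidden),
            "c": np.zeros(1),
        }

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (B, T, d) -> scores (B,); optionally the BPTT cache."""
        p = self.params
        B, T, _ = x.shape
        h = np.zeros((B, self.hidden))
        cache = []
        for t in range(T):
            xt = x[:, t, :]
            z = _sigmoid(xt @ p["wz"] + h @ p["uz"] + p["bz"])
            r = _sigmoid(xt @ p["wr"] + h @ p["ur"] + p["br"])
            hb = np.tanh(xt @ p["wh"] + (r * h) @ p["uh"] + p["bh"])
            h_new = (1.0 - z) * h + z * hb
            if want_cache:
                cache.append((xt, h, z, r, hb))
            h = h_new
        out = _sigmoid(h @ p["v"] + p["c"][0])
        return (out, h, cache) if want_cache else out

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        p = self.params
        out, h_final, cache = self.forward(x, want_cache=True)
        B = y.size
        loss = float(np.mean((out - y) ** 2))
        g = {k: np.zeros_like(v) for k, v in p.items()}
        d_o = 2.0 * (out - y) * out * (1.0 - out) / B
        g["v"] = h_final.T @ d_o
        g["c"][0] = d_o.sum()
        dh = d_o[:, None] * p["v"][None, :]
        for xt, h_prev, z, r, hb in reversed(cache):
            dhb = dh * z * (1.0 - hb**2)
            dz = dh * (hb - h_prev) * z * (1.0 - z)
            dh_prev = dh * (1.0 - z)
            g["wh"] += xt.T @ dhb
            g["uh"] += (r * h_prev).T @ dhb
            g["bh"] += dhb.sum(axis=0)
            drh = dhb @ p["uh"].T
            dr = drh * h_prev * r * (1.0 - r)
            dh_prev += drh * r
            g["wz"] += xt.T @ dz
            g["uz"] += h_prev.T @ dz
            g["bz"] += dz.sum(axis=0)
            g["wr"] += xt.T @ dr
            g["ur"] += h_prev.T @ dr
            g["br"] += dr.sum(axis=0)
            dh_prev += dz @ p["uz"].T + dr @ p["ur"].T
            dh = dh_prev
        return loss, g


class SequenceModel:
    """Ensemble of GRU members; prediction is the mean member score in [0, 1]."""

    def __init__(self, members: list[GRUNetwork], encoding: str = "blosum",
                 max_median: float | None = None):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = members
        self.encoding = encoding
        self.max_median = max_median

    def predict(self, peptides: list[str]) -> np.ndarray:
        x = sequence_features(peptides, self.encoding).astype(np.float64)
        acc = np.zeros(x.shape[0])
        for m in self.members:
            acc += m.predict(x)
        return acc / len(self.members)

    def score_peptide(self, peptide: str) -> float:
        return float(self.predict([peptide])[0])


def _train_gru(
    x: np.ndarray,
    y: np.ndarray,
    xv: np.ndarray,
    yv: np.ndarray,
    config: SeqTrainConfig,
    rng: np.random.Generator,
) -> GRUNetwork:
    net = GRUNetwork(x.shape[2], config.hidden_size, rng, config.init_scale)
    # Adam state
    m = {k: np.zeros_like(v) for k, v in net.params.items()}
    v2 = {k: np.zeros_like(v) for k, v in net.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_val = np.inf
    best_params = {k: p.copy() for k, p in net.params.items()}
    stale = 0
    n = x.shape[0]
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            loss, grads = net.loss_and_grads(x[sel], y[sel])
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            step += 1
            for k in net.params:
                m[k] = b1 * m[k] + (1 - b1) * grads[k]
                v2[k] = b2 * v2[k] + (1 - b2) * grads[k] ** 2
                mhat = m[k] / (1 - b1**step)
                vhat = v2[k] / (1 - b2**step)
                net.params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        val = float(np.mean((net.predict(xv) - yv) ** 2))
        if val < best_val - 1e-7:
            best_val = val
            best_params = {k: p.copy() for k, p in net.params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    net.params = best_params
    return net


def train_sequence_model(
    data: ArrayDataset,
    partition: Partition,
    config: SeqTrainConfig | None = None,
    seed: int = 0,
) -> SequenceModel:
    """Train the GRU ensemble with the same fold discipline as the core model."""
    config = config or SeqTrainConfig()
    if data.target is None:
        raise ValueError("dataset must be normalized before training")
    folds = partition.fold_names
    x = sequence_features(data.peptides, config.encoding).astype(np.float64)
    y = np.asarray(data.target, dtype=np.float64)
    fold_of = np.array(
        [folds.index(s) if s in folds else -1 for s in partition.subset], dtype=np.int64
    )
    seed_seq = np.random.SeedSequence(seed)
    members: list[GRUNetwork] = []
    for f in range(len(folds)):
        train_mask = (fold_of >= 0) & (fold_of != f)
        val_mask = fold_of == f
        if val_mask.sum() == 0 or train_mask.sum() == 0:
            raise ValueError(f"fold {folds[f]} is empty")
        for child in seed_seq.spawn(config.n_restarts):
            rng = np.random.default_rng(child)
            members.append(
                _train_gru(x[train_mask], y[train_mask], x[val_mask], y[val_mask], config, rng)
            )
    return SequenceModel(members, encoding=config.encoding, max_median=data.max_median)
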