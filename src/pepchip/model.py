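"""Binding-core neural network trained on normalized chip intensities.

The primary predictor follows the NNAlign lineage: each candidate 9-mer
window (binding core) of a peptide is pushed through a small feed-forward
network, the peptide's score is the maximum over its windows, and during
training the gradient flows only through the max-scoring window.  The
final model is an ensemble over hidden-layer sizes, random restarts and
cross-validation folds; the ensemble prediction is the unweighted mean of
member predictions, each in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .alphabet import ENCODINGS, N_RESIDUES, encode_matrix
from .arrays import ArrayDataset, back_transform
from .motif import CORE_LENGTH
from .partition import Partition


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def window_features(peptides: list[str], encoding: str = "blosum") -> np.ndarray:
    """Encode every core-length window of every peptide.

    Returns an (n_peptides, n_windows, 9 * 20) float32 array; a 13-mer
    yields 5 windows.
    """
    table = ENCODINGS[encoding].astype(np.float32)
    idx = encode_matrix(peptides)
    win_idx = sliding_window_view(idx, CORE_LENGTH, axis=1)  # (n, n_win, 9)
    n, n_win, k = win_idx.shape
    return table[win_idx].reshape(n, n_win, k * N_RESIDUES)


@dataclass
class CoreNetwork:
    """One ensemble member: a single-hidden-layer sigmoid network."""

    w1: np.ndarray  # (d_in, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float

    def window_scores(self, feats: np.ndarray) -> np.ndarray:
        """Scores of each window: feats (..., d_in) -> (...)."""
        hidden = _sigmoid(feats @ self.w1 + self.b1)
        return _sigmoid(hidden @ self.w2 + self.b2)

    def predict(self, feats: np.ndarray) -> np.ndarray:
        """Max-over-windows peptide scores: feats (n, n_win, d_in) -> (n,)."""
        return self.window_scores(feats).max(axis=1)


@dataclass
class TrainConfig:
    """Hyperparameters of core-model training.

    Defaults follow the NNAlign lineage: hidden sizes {20, 40, 60}, 10
    random restarts per size, plain SGD on the squared error, early
    stopping with patience 20 on the held-out fold.  The step size of 1.0
    compensates for the small gradients of the sigmoid/squared-error
    pairing; smaller steps underfit within the epoch budget.  Desk-scale
    runs override ``hidden_sizes``/``n_restarts`` downward.
    """

    hidden_sizes: tuple[int, ...] = (20, 40, 60)
    n_restarts: int = 10
    learning_rate: float = 1.0
    batch_size: int = 128
    max_epochs: int = 300
    patience: int = 20
    encoding: str = "blosum"
    init_scale: float = 0.1


class BindingModel:
    """Ensemble of core networks mapping a peptide to a normalized score."""

    def __init__(self, members: list[CoreNetwork], encoding: str = "blosum",
                 max_median: float | None = None):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = members
        self.encoding = encoding
        self.max_median = max_median

    def predict(self, peptides: list[str]) -> np.ndarray:
        """Mean over members of the max-over-windows score, in [0, 1]."""
        feats = window_features(peptides, self.encoding)
        return self.predict_from_features(feats)

    def predict_from_features(self, feats: np.ndarray) -> np.ndarray:
        acc = np.zeros(feats.shape[0])
        for m in self.members:
            acc += m.predict(feats)
        return acc / len(self.members)

    def score_peptide(self, peptide: str) -> float:
        return float(self.predict([peptide])[0])

    # ------------------------------------------------------------ serialization
    def save(self, path: str | Path) -> None:
        payload = {
            "encoding": self.encoding,
            "max_median": self.max_median,
            "members": [
                {
                    "w1": np.asarray(m.w1, dtype=float).tolist(),
                    "b1": np.asarray(m.b1, dtype=float).tolist(),
                    "w2": np.asarray(m.w2, dtype=float).tolist(),
                    "b2": float(m.b2),
                }
                for m in self.members
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "BindingModel":
        payload = json.loads(Path(path).read_text())
        members = [
            CoreNetwork(
                w1=np.array(m["w1"], dtype=np.float32),
                b1=np.array(m["b1"], dtype=np.float32),
                w2=np.array(m["w2"], dtype=np.float32),
                b2=float(m["b2"]),
            )
            for m in payload["members"]
        ]
        return cls(members, encoding=payload["encoding"], max_median=payload["max_median"])


def _train_member(
    feats: np.ndarray,
    targets: np.ndarray,
    val_feats: np.ndarray,
    val_targets: np.ndarray,
    hidden: int,
    config: TrainConfig,
    rng: np.random.Generator,
) -> CoreNetwork:
    """SGD on squared error, gradient through the max-scoring window only."""
    d_in = feats.shape[2]
    w1 = rng.normal(0.0, config.init_scale, size=(d_in, hidden)).astype(np.float32)
    b1 = np.zeros(hidden, dtype=np.float32)
    w2 = rng.normal(0.0, config.init_scale, size=hidden).astype(np.float32)
    b2 = 0.0

    n = feats.shape[0]
    lr = config.learning_rate
    best = (np.inf, w1.copy(), b1.copy(), w2.copy(), b2)
    stale = 0
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            x = feats[sel]  # (B, n_win, d)
            y = targets[sel]
            hidden_act = _sigmoid(x @ w1 + b1)          # (B, n_win, h)
            out = _sigmoid(hidden_act @ w2 + b2)        # (B, n_win)
            wstar = out.argmax(axis=1)
            rows = np.arange(sel.size)
            o = out[rows, wstar]
            h = hidden_act[rows, wstar]                 # (B, h)
            xs = x[rows, wstar]                         # (B, d)
            # squared-error gradient through the selected window
            d_o = (2.0 * (o - y) * o * (1.0 - o)).astype(np.float32)
            g_w2 = h.T @ d_o / sel.size
            g_b2 = d_o.mean()
            d_h = (d_o[:, None] * w2[None, :] * h * (1.0 - h)).astype(np.float32)
            g_w1 = xs.T @ d_h / sel.size
            g_b1 = d_h.mean(axis=0)
            if not np.isfinite(g_b2):
                raise FloatingPointError("non-finite training gradient")
            w1 -= lr * g_w1
            b1 -= lr * g_b1
            w2 -= lr * g_w2
            b2 -= lr * g_b2
        member = CoreNetwork(w1, b1, w2, b2)
        val_mse = float(np.mean((member.predict(val_feats) - val_targets) ** 2))
        if val_mse < best[0] - 1e-7:
            best = (val_mse, w1.copy(), b1.copy(), w2.copy(), b2)
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    _, w1, b1, w2, b2 = best
    return CoreNetwork(w1, b1, w2, b2)


def train_core_model(
    data: ArrayDataset,
    partition: Partition,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> BindingModel:
    """Train the fold ensemble on a normalized dataset.

    For each cross-validation fold, members (one per hidden size x restart)
    are trained on the remaining folds with early stopping on the held-out
    fold; the test subset is never touched.  The returned ensemble pools
    all fold members and records the training ``max_median`` for
    back-transformation.  Deterministic given ``seed``.
    """
    config = config or TrainConfig()
    if data.target is None:
        raise ValueError("dataset must be normalized before training")
    if partition.peptides != data.peptides:
        raise ValueError("partition and dataset peptide order differ")
    folds = partition.fold_names
    if len(folds) < 2:
        raise ValueError("training requires at least 2 folds")

    feats = window_features(data.peptides, config.encoding)
    targets = np.asarray(data.target, dtype=np.float32)
    fold_of = np.array(
        [folds.index(s) if s in folds else -1 for s in partition.subset], dtype=np.int64
    )

    seed_seq = np.random.SeedSequence(seed)
    members: list[CoreNetwork] = []
    for f in range(len(folds)):
        train_mask = (fold_of >= 0) & (fold_of != f)
        val_mask = fold_of == f
        if val_mask.sum() == 0 or train_mask.sum() == 0:
            raise ValueError(f"fold {folds[f]} is empty")
        tr_feats, tr_y = feats[train_mask], targets[train_mask]
        va_feats, va_y = feats[val_mask], targets[val_mask]
        for hidden in config.hidden_sizes:
            for child in seed_seq.spawn(config.n_restarts):
                rng = np.random.default_rng(child)
                members.append(
                    _train_member(tr_feats, tr_y, va_feats, va_y, hidden, config, rng)
                )
    return BindingModel(members, encoding=config.encoding, max_median=data.max_median)


def evaluate(model: BindingModel, test: ArrayDataset) -> dict:
    """PCC and SCC of back-transformed predictions against test intensities.

    Predictions and targets are mapped back onto the intensity scale with
    the training max_median before computing the Pearson correlation; the
    Spearman correlation is invariant under this monotone map.
    """
    if test.target is None:
        raise ValueError("test dataset must be normalized")
    preds = np.clip(model.predict(test.peptides), 0.0, 1.0)
    max_median = model.max_median if model.max_median is not None else test.max_median
    pred_int = back_transform(preds, max_median)
    true_int = back_transform(np.clip(test.target, 0, 1), max_median)
    if np.ptp(pred_int) == 0 or np.ptp(true_int) == 0:
        return {"pcc": None, "scc": None, "note": "degenerate constant predictions"}
    pcc = float(stats.pearsonr(pred_int, true_int)[0])
    scc = float(stats.spearmanr(pred_int, true_int)[0])
    return {"pcc": pcc, "scc": scc, "n": len(test)}


def bootstrap_compare(
    preds_a: np.ndarray,
    preds_b: np.ndarray,
    targets: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
    metric: str = "pearson",
    two_sided: bool = False,
) -> float:
    """Non-parametric bootstrap test of correlation difference between models.

    Resamples observation indices with replacement and reports the fraction
    of replicates in which model B's correlation with the targets is at
    least model A's (one-sided; ``two_sided`` doubles the smaller tail).
    The study-scale setting is 1,000,000 iterations; 10,000 is the
    desk-scale default.
    """
    preds_a = np.asarray(preds_a, float)
    preds_b = np.asarray(preds_b, float)
    targets = np.asarray(targets, float)
    n = targets.size
    if preds_a.size != n or preds_b.size != n:
        raise ValueError("prediction and target vectors must have equal length")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if n < 10:
        raise ValueError("too few observations to resample")
    rng = np.random.default_rng(seed)

    def _corr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if metric == "spearman":
            x = np.argsort(np.argsort(x, axis=1), axis=1).astype(float)
            y = np.argsort(np.argsort(y, axis=1), axis=1).astype(float)
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        return (xc * yc).sum(axis=1) / denom

    count = 0.0
    chunk = max(1, min(n_boot, 2_000_000 // max(n, 1)))
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(m, n))
        ca = _corr(preds_a[idx], targets[idx])
        cb = _corr(preds_b[idx], targets[idx])
        # ties count half so identical models give p = 0.5
        count += float(np.sum(cb > ca)) + 0.5 * float(np.sum(cb == ca))
        done += m
    p = count / n_boot
    if two_sided:
        p = 2.0 * min(p, 1.0 - p)
    return float(p)
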