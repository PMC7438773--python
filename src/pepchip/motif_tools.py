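"""Motif extraction from trained models and motif comparison.

A trained model's binding motif is estimated the way sequence logos are
built from predictors: score a large pool of random natural 13-mers, keep
the top 1%, align their 9-mer binding cores with a simulated-annealing
Gibbs sampler maximizing Kullback-Leibler information content against the
background, and summarize the alignment as a 9 x 20 log-odds PSSM.
Motifs from different models are compared by Pearson correlation of the
flattened matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alphabet import N_RESIDUES, encode_matrix
from .motif import CORE_LENGTH, UNIFORM_BACKGROUND, Motif, pssm_correlation  # noqa: F401
from .synthetic import generate_peptide_library


def sample_scoring_pool(
    n: int,
    seed: int = 0,
    source: list[str] | None = None,
    length: int = 13,
) -> list[str]:
    """Draw a pool of 13-mers for motif estimation.

    With ``source`` sequences (e.g. a proteome read from FASTA), windows of
    the requested length are sampled uniformly over all windows of all
    source sequences.  Without a source, random natural peptides are
    generated.  Deterministic given ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if source is None:
        return generate_peptide_library(n, length=length, seed=seed)
    starts: list[tuple[int, int]] = []
    for si, seq in enumerate(source):
        if len(seq) >= length:
            starts.extend((si, o) for o in range(len(seq) - length + 1))
    if not starts:
        raise ValueError("no source sequence long enough to sample from")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(starts), size=n)
    return [source[starts[k][0]][starts[k][1] : starts[k][1] + length] for k in picks]


def select_top_fraction(model, pool: list[str], fraction: float = 0.01) -> list[str]:
    """Highest-scoring ceil(fraction * n) peptides of the pool under the model.

    Ties at the cutoff are broken by lexicographic peptide order.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if len(pool) < 1.0 / fraction:
        raise ValueError("pool too small for the requested fraction")
    scores = np.asarray(model.predict(pool), dtype=float)
    n_top = math.ceil(fraction * len(pool))
    order = sorted(range(len(pool)), key=lambda i: (-scores[i], pool[i]))
    return [pool[i] for i in order[:n_top]]


@dataclass
class CoreAlignment:
    """Aligned binding cores: one core-length offset per peptide."""

    peptides: list[str]
    offsets: np.ndarray
    core_length: int = CORE_LENGTH
    background: np.ndarray = None

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        if self.background is None:
            self.background = UNIFORM_BACKGROUND.copy()
        for p, o in zip(self.peptides, self.offsets):
            if not 0 <= o <= len(p) - self.core_length:
                raise ValueError("offset outside the peptide")

    def cores(self) -> list[str]:
        return [p[o : o + self.core_length] for p, o in zip(self.peptides, self.offsets)]

    def frequencies(self, pseudocount_weight: float = 1.0) -> np.ndarray:
        """Per-position residue frequencies with flat pseudocounts."""
        idx = encode_matrix(self.cores())
        counts = np.zeros((self.core_length, N_RESIDUES))
        for pos in range(self.core_length):
            counts[pos] = np.bincount(idx[:, pos], minlength=N_RESIDUES)
        n = len(self.peptides)
        if pseudocount_weight > 0:
            freq = (counts + pseudocount_weight * self.background[None, :]) / (
                n + pseudocount_weight
            )
        else:
            freq = np.maximum(counts / n, 1e-9)  # guard log(0) at zero pseudocount
            freq = freq / freq.sum(axis=1, keepdims=True)
        return freq

    def information_content(self, pseudocount_weight: float = 1.0) -> np.ndarray:
        """Kullback-Leibler information content per position, in bits."""
        freq = self.frequencies(pseudocount_weight)
        return np.sum(freq * np.log2(freq / self.background[None, :]), axis=1)


def _alignment_ic(counts: np.ndarray, n: int, background: np.ndarray, alpha: float) -> float:
    freq = (counts + alpha * background[None, :]) / (n + alpha)
    return float(np.sum(freq * np.log2(freq / background[None, :])))


def gibbs_core_alignment(
    peptides: list[str],
    core_length: int = CORE_LENGTH,
    n_iterations: int = 100,
    seed: int = 0,
    temperature: tuple[float, float] = (1.5, 0.05),
    background: np.ndarray | None = None,
    pseudocount_weight: float = 1.0,
) -> CoreAlignment:
    """Sample per-peptide core offsets maximizing alignment information.

    Gibbs sampling with a linearly annealed temperature: in each sweep every
    peptide's core is withdrawn from the profile, each candidate offset is
    scored by its log-odds against the leave-one-out profile, and a new
    offset is drawn from the Boltzmann distribution at the current
    temperature.  The best-scoring alignment (by total KL information
    content, including the initial state) encountered anywhere in the run
    is returned, so the result never falls below the initialization.
    Deterministic given ``seed``.
    """
    if not peptides:
        raise ValueError("empty peptide list")
    if any(len(p) < core_length for p in peptides):
        raise ValueError("all peptides must be at least core_length long")
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    rng = np.random.default_rng(seed)
    n = len(peptides)
    idx_list = [encode_matrix([p])[0] for p in peptides]
    n_windows = np.array([len(p) - core_length + 1 for p in peptides])
    offsets = np.array([rng.integers(0, w) for w in n_windows])

    pos = np.arange(core_length)
    counts = np.zeros((core_length, N_RESIDUES))
    for i in range(n):
        counts[pos, idx_list[i][offsets[i] : offsets[i] + core_length]] += 1

    alpha = pseudocount_weight
    log_bg = np.log2(bg)
    best_ic = _alignment_ic(counts, n, bg, alpha)
    best_offsets = offsets.copy()

    t_hi, t_lo = temperature
    for sweep in range(n_iterations):
        t = t_hi + (t_lo - t_hi) * sweep / max(n_iterations - 1, 1)
        for i in rng.permutation(n):
            seq = idx_list[i]
            counts[pos, seq[offsets[i] : offsets[i] + core_length]] -= 1
            # leave-one-out log-odds of every candidate window
            log_q = np.log2((counts + alpha * bg[None, :]) / (n - 1 + alpha))
            nw = n_windows[i]
            scores = np.empty(nw)
            for o in range(nw):
                scores[o] = (log_q[pos, seq[o : o + core_length]] - log_bg[seq[o : o + core_length]]).sum()
            w = np.exp((scores - scores.max()) / max(t, 1e-6))
            offsets[i] = rng.choice(nw, p=w / w.sum())
            counts[pos, seq[offsets[i] : offsets[i] + core_length]] += 1
        ic = _alignment_ic(counts, n, bg, alpha)
        if ic > best_ic:
            best_ic = ic
            best_offsets = offsets.copy()

    return CoreAlignment(
        peptides=list(peptides), offsets=best_offsets, core_length=core_length, background=bg
    )


def build_pssm(
    alignment: CoreAlignment,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
) -> Motif:
    """Log2-odds PSSM of the aligned cores against the background."""
    if not alignment.peptides:
        raise ValueError("empty alignment")
    bg = alignment.background if background is None else np.asarray(background, float)
    freq = alignment.frequencies(pseudocount_weight)
    weights = np.log2(freq / bg[None, :])
    return Motif(weights=weights, background=bg)


def extract_motif(
    model,
    pool: list[str] | None = None,
    pool_size: int = 100_000,
    fraction: float = 0.01,
    n_iterations: int = 100,
    seed: int = 0,
    pseudocount_weight: float = 1.0,
) -> Motif:
    """Full motif-extraction pipeline: pool -> top fraction -> Gibbs -> PSSM."""
    if pool is None:
        pool = sample_scoring_pool(pool_size, seed=seed)
    top = select_top_fraction(model, pool, fraction)
    alignment = gibbs_core_alignment(top, n_iterations=n_iterations, seed=seed + 1)
    return build_pssm(alignment, pseudocount_weight)
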