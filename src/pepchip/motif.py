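"""Binding-motif container: a positions x 20 log-odds matrix (PSSM).

A class II binding motif is represented as a 9 x 20 position-specific scoring
matrix of log2-odds scores against a background residue distribution.  The
same container holds ground-truth planted motifs, motifs extracted from
trained models, and motifs read from text files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .alphabet import AMINO_ACIDS, N_RESIDUES, encode_indices

CORE_LENGTH = 9

UNIFORM_BACKGROUND = np.full(N_RESIDUES, 1.0 / N_RESIDUES)


@dataclass
class Motif:
    """Position-specific scoring matrix with its background distribution.

    Parameters
    ----------
    weights
        (core_length, 20) array of log2-odds scores, columns ordered as
        :data:`pepchip.alphabet.AMINO_ACIDS`.
    background
        Length-20 residue frequencies, positive and summing to 1.
    """

    weights: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.weights.ndim != 2 or self.weights.shape[1] != N_RESIDUES:
            raise ValueError(f"weights must be (core_length, {N_RESIDUES}), got {self.weights.shape}")
        if self.background.shape != (N_RESIDUES,):
            raise ValueError("background must have 20 entries")
        if np.any(self.background <= 0):
            raise ValueError("background frequencies must be positive")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    @property
    def core_length(self) -> int:
        return self.weights.shape[0]

    def score_core(self, core: str) -> float:
        """Log-odds score of a single core (length must equal core_length)."""
        idx = encode_indices(core)
        if idx.size != self.core_length:
            raise ValueError(f"core must have length {self.core_length}")
        return float(self.weights[np.arange(self.core_length), idx].sum())

    def score_windows(self, peptide_idx: np.ndarray) -> np.ndarray:
        """Scores of all core-length windows of an index-encoded peptide."""
        L = peptide_idx.size
        k = self.core_length
        if L < k:
            raise ValueError("peptide shorter than motif core")
        n_win = L - k + 1
        out = np.empty(n_win)
        pos = np.arange(k)
        for o in range(n_win):
            out[o] = self.weights[pos, peptide_idx[o : o + k]].sum()
        return out

    def best_window_score(self, peptide: str) -> float:
        """Maximum log-odds score over all core-length windows of the peptide."""
        return float(self.score_windows(encode_indices(peptide)).max())

    def implied_frequencies(self) -> np.ndarray:
        """Per-position residue distributions implied by the log-odds weights.

        Inverts the log-odds map: p(a) proportional to background(a) * 2**w(a).
        """
        unnorm = self.background[None, :] * np.exp2(self.weights)
        return unnorm / unnorm.sum(axis=1, keepdims=True)

    def information_content(self) -> np.ndarray:
        """Kullback-Leibler information content per position, in bits."""
        freqs = self.implied_frequencies()
        return np.sum(freqs * np.log2(freqs / self.background[None, :]), axis=1)


def pssm_correlation(a: Motif | np.ndarray, b: Motif | np.ndarray) -> float:
    """Pearson correlation between two motifs over their flattened entries.

    Two 9 x 20 matrices are compared as 180-vectors.  Raises if either matrix
    is constant (correlation undefined).
    """
    wa = a.weights if isinstance(a, Motif) else np.asarray(a, dtype=float)
    wb = b.weights if isinstance(b, Motif) else np.asarray(b, dtype=float)
    if wa.shape != wb.shape:
        raise ValueError(f"shape mismatch: {wa.shape} vs {wb.shape}")
    fa, fb = wa.ravel(), wb.ravel()
    if np.ptp(fa) == 0 or np.ptp(fb) == 0:
        raise ValueError("correlation undefined for a constant matrix")
    return float(stats.pearsonr(fa, fb)[0])


def write_pssm(motif: Motif, path: str | Path, n_sequences: int | None = None) -> None:
    """Write a motif in the package's tab-separated PSSM text format.

    Format: '#' comment lines carrying metadata (background frequencies,
    optionally the number of aligned sequences), one header line with the
    alphabet order, then core_length rows of 20 tab-separated log2-odds.
    """
    with open(path, "w") as fh:
        fh.write(_format_pssm(motif, n_sequences))


def _format_pssm(motif: Motif, n_sequences: int | None = None) -> str:
    buf = io.StringIO()
    bg = " ".join(f"{x:.6g}" for x in motif.background)
    buf.write(f"# background: {bg}\n")
    if n_sequences is not None:
        buf.write(f"# n_sequences: {n_sequences}\n")
    buf.write("\t".join(AMINO_ACIDS) + "\n")
    for row in motif.weights:
        buf.write("\t".join(f"{x:.6f}" for x in row) + "\n")
    return buf.getvalue()


def read_pssm(path: str | Path) -> Motif:
    """Read a motif written by :func:`write_pssm`."""
    background = UNIFORM_BACKGROUND.copy()
    rows: list[list[float]] = []
    header: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("background:"):
                background = np.array([float(x) for x in body.split(":", 1)[1].split()])
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            if "".join(header) != AMINO_ACIDS:
                raise ValueError("PSSM alphabet order does not match the canonical order")
            continue
        rows.append([float(x) for x in fields])
    if header is None or not rows:
        raise ValueError("malformed PSSM file")
    return Motif(weights=np.array(rows), background=background)
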