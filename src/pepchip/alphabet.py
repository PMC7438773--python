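"""Canonical amino-acid alphabet and numeric peptide encodings.

Every matrix in this package (motifs, PSSMs, composition vectors) uses the
20 standard residues in the fixed order :data:`AMINO_ACIDS`.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

#: The 20 standard amino acids, in the canonical column order used by all
#: position-specific matrices in this package.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

N_RESIDUES: int = len(AMINO_ACIDS)

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def is_standard(peptide: str) -> bool:
    """True if every residue of ``peptide`` is one of the 20 standard amino acids."""
    return all(aa in AA_INDEX for aa in peptide)


def encode_indices(peptide: str) -> np.ndarray:
    """Map a peptide to an int array of residue indices into :data:`AMINO_ACIDS`.

    Raises
    ------
    ValueError
        If the peptide contains a non-standard residue (e.g. 'X', 'B', 'Z').
    """
    try:
        return np.fromiter((AA_INDEX[aa] for aa in peptide), dtype=np.int64, count=len(peptide))
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in peptide {peptide!r}") from exc


def encode_matrix(peptides: list[str]) -> np.ndarray:
    """Encode equal-length peptides as an (n, L) index matrix."""
    if not peptides:
        raise ValueError("empty peptide list")
    length = len(peptides[0])
    out = np.empty((len(peptides), length), dtype=np.int64)
    for i, p in enumerate(peptides):
        if len(p) != length:
            raise ValueError("peptides must have equal length")
        out[i] = encode_indices(p)
    return out


def _build_blosum_features() -> np.ndarray:
    """Per-residue BLOSUM62 profile rows, rescaled to roughly unit range."""
    blosum = substitution_matrices.load("BLOSUM62")
    feat = np.empty((N_RESIDUES, N_RESIDUES), dtype=np.float64)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            feat[i, j] = blosum[a, b]
    return feat / 10.0


#: (20, 20) matrix: row i is the BLOSUM62 substitution profile of residue i,
#: divided by 10 so features live in roughly [-1, 1.5].
BLOSUM_FEATURES: np.ndarray = _build_blosum_features()

#: (20, 20) identity: row i is the one-hot encoding of residue i.
ONEHOT_FEATURES: np.ndarray = np.eye(N_RESIDUES)

ENCODINGS: dict[str, np.ndarray] = {
    "blosum": BLOSUM_FEATURES,
    "onehot": ONEHOT_FEATURES,
}
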