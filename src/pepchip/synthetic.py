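"""Synthetic chip data with planted class II binding motifs.

Emulates the statistical structure of a high-density peptide-microarray
experiment: a library of random natural 13-mers (filtered for poly-residue
runs), triplicate intensities on a 0-254 scale generated from a planted
9-position binding motif through a saturating response curve plus
multiplicative replicate noise, and benchmark source proteins with
implanted ligands for rank-based evaluation.

The forward model is an emulation for testing the downstream pipeline, not
a claim about scanner physics: the latent binding signal of a peptide is
the maximum motif log-odds score over its 9-mer windows (the binding-core
assumption), pushed through a logistic saturation onto the intensity scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AMINO_ACIDS, N_RESIDUES, encode_matrix
from .arrays import ArrayDataset
from .motif import CORE_LENGTH, UNIFORM_BACKGROUND, Motif

#: No run of 4 or more identical consecutive residues (e.g. RRRR) is allowed:
#: such peptides are hard to synthesize and bind unspecifically.
POLY_RUN = re.compile(r"(.)\1{3}")


@dataclass
class SyntheticArraySpec:
    """Parameters of a simulated array experiment.

    ``noise_sd`` is the log-scale standard deviation of the multiplicative
    replicate noise; ``midpoint``/``slope`` shape the logistic mapping of
    latent motif scores onto [0, dynamic_range] (midpoint ``None`` places it
    at half the motif's maximum attainable score, which leaves most random
    peptides in the low-intensity tail and makes the intensity histogram
    right-skewed like real chip readouts).  ``quantize`` rounds intensities
    to integers like the real scanner; it is off by default so that the
    noiseless intensity ranking matches the latent score ranking exactly.
    """

    n_peptides: int = 5000
    peptide_length: int = 13
    n_replicates: int = 3
    # 0.3 reproduces the replicate consistency of real chip readouts
    # (mean CoV around 0.135, combined replicate correlation > 0.99)
    noise_sd: float = 0.3
    dynamic_range: float = 254.0
    midpoint: float | None = None
    slope: float = 1.5
    quantize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peptides <= 0:
            raise ValueError("n_peptides must be positive")
        if self.peptide_length < CORE_LENGTH:
            raise ValueError(f"peptide_length must be >= {CORE_LENGTH}")
        if self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be positive")


def generate_motif(
    seed: int,
    n_anchors: int,
    anchor_strength: float = 3.0,
    core_length: int = CORE_LENGTH,
    background: np.ndarray | None = None,
) -> Motif:
    """Plant a binding motif with ``n_anchors`` anchor positions.

    The motif is the log2-odds matrix of an explicit per-position residue
    distribution, the way real binding motifs are summarized: at an anchor
    position, one or two favored residues each carry probability mass
    background * 2**anchor_strength (log-odds exactly +anchor_strength) and
    the remaining mass is spread evenly over the other residues (which are
    correspondingly disfavored); non-anchor positions are flat (zero
    log-odds).  Deterministic given ``seed``.
    """
    if not 0 <= n_anchors <= core_length:
        raise ValueError(f"n_anchors must be in [0, {core_length}]")
    if n_anchors > 0 and anchor_strength <= 0:
        raise ValueError("anchor_strength must be positive")
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    rng = np.random.default_rng(seed)
    weights = np.zeros((core_length, N_RESIDUES))
    anchor_positions = rng.choice(core_length, size=n_anchors, replace=False)
    for pos in anchor_positions:
        k = int(rng.integers(1, 3))  # one or two favored residues
        favored = rng.choice(N_RESIDUES, size=k, replace=False)
        p_favored = bg[favored] * 2.0**anchor_strength
        mass = p_favored.sum()
        if mass >= 1.0:
            raise ValueError(
                "anchor_strength too large: favored residues would carry "
                f"probability mass {mass:.2f} >= 1"
            )
        others = np.setdiff1d(np.arange(N_RESIDUES), favored)
        p = np.empty(N_RESIDUES)
        p[favored] = p_favored
        p[others] = (1.0 - mass) / others.size
        weights[pos, :] = np.log2(p / bg)
    return Motif(weights=weights, background=bg)


def passes_poly_filter(peptide: str) -> bool:
    """True if the peptide has no run of >= 4 identical consecutive residues."""
    return POLY_RUN.search(peptide) is None


def generate_peptide_library(
    n: int, length: int = 13, seed: int = 0, max_attempts: int = 200
) -> list[str]:
    """Draw ``n`` distinct random natural peptides passing the poly-run filter.

    Residues are sampled uniformly over the 20 standard amino acids;
    candidates containing a poly-residue run (RRRR etc.) or duplicating an
    earlier peptide are redrawn.  Deterministic given ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[str] = []
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    for _ in range(max_attempts):
        batch = aa[rng.integers(0, N_RESIDUES, size=(max(n - len(out), 16), length))]
        for row in batch:
            pep = row.tobytes().decode()
            if pep in seen or not passes_poly_filter(pep):
                continue
            seen.add(pep)
            out.append(pep)
            if len(out) == n:
                return out
    raise RuntimeError(f"could not generate {n} distinct filtered peptides of length {length}")


def latent_scores(motif: Motif, peptides: list[str]) -> np.ndarray:
    """Best 9-mer-window motif score for each peptide (vectorized)."""
    idx = encode_matrix(peptides)
    n, L = idx.shape
    k = motif.core_length
    if L < k:
        raise ValueError("peptides shorter than the motif core")
    pos = np.arange(k)
    window_scores = np.empty((n, L - k + 1))
    for o in range(L - k + 1):
        window_scores[:, o] = motif.weights[pos, idx[:, o : o + k]].sum(axis=1)
    # round away summation-order noise so mathematically equal window scores
    # tie exactly (peptides with the same best core get identical intensity)
    return np.round(window_scores.max(axis=1), 9)


def _response_curve(scores: np.ndarray, spec: SyntheticArraySpec, motif: Motif) -> np.ndarray:
    mid = spec.midpoint
    if mid is None:
        mid = 0.5 * float(motif.weights.max(axis=1).sum())
    return spec.dynamic_range / (1.0 + np.exp(-(scores - mid) / spec.slope))


def simulate_intensities(
    motif: Motif, peptides: list[str], spec: SyntheticArraySpec
) -> ArrayDataset:
    """Simulate replicate chip intensities for a peptide library.

    Latent score -> logistic saturation onto [0, dynamic_range] -> per
    replicate multiplicative log-normal noise of log-scale sd ``noise_sd``
    -> clip to the dynamic range.  Deterministic given ``spec.seed``.
    """
    if not peptides:
        raise ValueError("empty peptide list")
    rng = np.random.default_rng(spec.seed)
    scores = latent_scores(motif, peptides)
    clean = _response_curve(scores, spec, motif)
    reps = np.repeat(clean[:, None], spec.n_replicates, axis=1)
    if spec.noise_sd > 0:
        reps = reps * np.exp(spec.noise_sd * rng.standard_normal(reps.shape))
    reps = np.clip(reps, 0.0, spec.dynamic_range)
    if spec.quantize:
        reps = np.round(reps)
    return ArrayDataset(peptides=list(peptides), replicates=reps)


def generate_benchmark_proteins(
    motif: Motif,
    n_proteins: int,
    protein_length: int = 200,
    ligand_length: int = 15,
    seed: int = 0,
    background: np.ndarray | None = None,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Random source proteins, each with one implanted high-affinity ligand.

    Each protein is a random background sequence (uniform residue
    frequencies by default) into which one ligand window is implanted.  The
    ligand carries a 9-mer core built from the motif's favored residues, so
    under the true motif it is (near-)top-scoring in its protein; with a
    flat motif the "ligand" is indistinguishable from background.  Returns
    the protein records and a table (peptide, protein_id, offset), offsets
    0-based.
    """
    if not 13 <= ligand_length <= 19:
        raise ValueError("ligand_length must be between 13 and 19")
    if protein_length <= ligand_length:
        raise ValueError("protein_length must exceed ligand_length")
    rng = np.random.default_rng(seed)
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    aa = np.array(list(AMINO_ACIDS))

    # residues within a small margin of each position's best score are "favored"
    favored = [
        np.flatnonzero(motif.weights[p] >= motif.weights[p].max() - 1e-6)
        for p in range(motif.core_length)
    ]

    records: list[SeqRecord] = []
    rows = []
    for i in range(n_proteins):
        core = "".join(aa[rng.choice(f)] for f in favored)
        flank_total = ligand_length - motif.core_length
        core_off = int(rng.integers(0, flank_total + 1))
        flanks = aa[rng.choice(N_RESIDUES, size=flank_total, p=bg)]
        ligand = "".join(flanks[:core_off]) + core + "".join(flanks[core_off:])
        protein = aa[rng.choice(N_RESIDUES, size=protein_length, p=bg)]
        offset = int(rng.integers(0, protein_length - ligand_length + 1))
        protein = "".join(protein[:offset]) + ligand + "".join(protein[offset + ligand_length :])
        pid = f"synthprot_{i:04d}"
        records.append(SeqRecord(Seq(protein), id=pid, description="synthetic benchmark protein"))
        rows.append({"peptide": ligand, "protein_id": pid, "offset": offset})
    return records, pd.DataFrame(rows)
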