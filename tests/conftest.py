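import numpy as np
import pytest

import pepchip as pc
from pepchip.model import TrainConfig


@pytest.fixture(scope="session")
def planted_motif():
    """4-anchor motif used across module tests (seed 1, strength 3 bits)."""
    return pc.generate_motif(seed=1, n_anchors=4, anchor_strength=3.0)


@pytest.fixture(scope="session")
def small_library():
    return pc.generate_peptide_library(2000, length=13, seed=7)


@pytest.fixture(scope="session")
def noiseless_dataset(planted_motif, small_library):
    spec = pc.SyntheticArraySpec(n_peptides=2000, noise_sd=0.0, seed=3)
    return pc.median_and_normalize(
        pc.simulate_intensities(planted_motif, small_library, spec)
    )


@pytest.fixture(scope="session")
def trained_small_model(planted_motif):
    """Core model trained on 5,000 noiseless peptides, 2-fold CV (shared)."""
    peps = pc.generate_peptide_library(5000, seed=2)
    spec = pc.SyntheticArraySpec(n_peptides=5000, noise_sd=0.0, seed=3)
    data = pc.median_and_normalize(pc.simulate_intensities(planted_motif, peps, spec))
    part = pc.assign_partition(peps, test_fraction=0.10, n_folds=2, seed=4)
    cfg = TrainConfig(hidden_sizes=(20,), n_restarts=1, max_epochs=200, patience=20)
    model = pc.train_core_model(data, part, cfg, seed=5)
    return model, data, part


class OracleModel:
    """Scores peptides by their true best-window motif score (rescaled to [0, 1])."""

    def __init__(self, motif):
        self.motif = motif
        self.max_median = 254.0

    def predict(self, peptides):
        from pepchip.synthetic import latent_scores

        s = latent_scores(self.motif, peptides)
        lo = self.motif.weights.min(axis=1).sum()
        hi = self.motif.weights.max(axis=1).sum()
        return (s - lo) / (hi - lo)


class HashScorer:
    """Deterministic pseudo-random scorer: i.i.d.-uniform-like, consistent per peptide."""

    def __init__(self, salt: int = 0):
        self.salt = salt
        self.max_median = 254.0

    def predict(self, peptides):
        out = np.empty(len(peptides))
        for i, p in enumerate(peptides):
            rng = np.random.default_rng(abs(hash((self.salt, p))) % (2**31))
            out[i] = rng.random()
        return out


@pytest.fixture(scope="session")
def oracle_model(planted_motif):
    return OracleModel(planted_motif)


@pytest.fixture(scope="session")
def hash_scorer():
    return HashScorer()
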