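"""Binding-core network: scoring semantics, training, evaluation, bootstrap."""

import numpy as np
import pytest

import pepchip as pc
from pepchip.model import (
    BindingModel,
    CoreNetwork,
    TrainConfig,
    bootstrap_compare,
    window_features,
)

from _oracles import pearson_textbook, spearman_textbook


def _random_member(seed, hidden=8, d_in=180):
    rng = np.random.default_rng(seed)
    return CoreNetwork(
        w1=rng.normal(0, 0.5, (d_in, hidden)),
        b1=rng.normal(0, 0.5, hidden),
        w2=rng.normal(0, 0.5, hidden),
        b2=float(rng.normal()),
    )


class TestScoring:
    def test_thirteen_mer_yields_five_windows(self):
        feats = window_features(["ACDEFGHIKLMNP"])
        assert feats.shape == (1, 5, 180)

    def test_zero_weight_network_scores_half(self):
        member = CoreNetwork(
            w1=np.zeros((180, 4)), b1=np.zeros(4), w2=np.zeros(4), b2=0.0
        )
        model = BindingModel([member])
        preds = model.predict(pc.generate_peptide_library(20, seed=1))
        assert np.allclose(preds, 0.5)

    def test_best_window_alone_scores_identically(self):
        member = _random_member(3)
        model = BindingModel([member])
        pep = "ACDEFGHIKLMNP"
        feats = window_features([pep])
        scores = member.window_scores(feats[0])
        best = int(np.argmax(scores))
        assert model.score_peptide(pep[best : best + 9]) == pytest.approx(
            float(scores[best]), abs=1e-12
        )

    def test_max_over_windows_matches_enumeration_oracle(self):
        """Member scores equal a brute-force max over explicitly listed 9-mers."""
        member = _random_member(4)
        model = BindingModel([member])
        peps = pc.generate_peptide_library(100, seed=5)
        preds = model.predict(peps)
        for pep, pred in zip(peps, preds):
            cores = [pep[o : o + 9] for o in range(5)]
            brute = max(
                float(member.window_scores(window_features([c])[0])[0]) for c in cores
            )
            assert pred == pytest.approx(brute, rel=1e-6)

    def test_nonstandard_residue_rejected(self):
        model = BindingModel([_random_member(6)])
        with pytest.raises(ValueError):
            model.predict(["ACDEFGHIKLMNX"])

    def test_ensemble_mean_semantics(self):
        m1, m2 = _random_member(7), _random_member(8)
        peps = pc.generate_peptide_library(10, seed=9)
        lhs = BindingModel([m1, m2]).predict(peps)
        rhs = 0.5 * (BindingModel([m1]).predict(peps) + BindingModel([m2]).predict(peps))
        assert np.allclose(lhs, rhs)


class TestTraining:
    def test_recovery_on_noiseless_planted_data(self, trained_small_model):
        model, data, part = trained_small_model
        report = pc.evaluate(model, data.subset(part.indices("test")))
        assert report["scc"] >= 0.8

    def test_permuted_targets_give_no_signal(self, planted_motif):
        peps = pc.generate_peptide_library(2000, seed=12)
        spec = pc.SyntheticArraySpec(n_peptides=2000, noise_sd=0.0, seed=13)
        data = pc.median_and_normalize(pc.simulate_intensities(planted_motif, peps, spec))
        rng = np.random.default_rng(14)
        data.target = rng.permutation(data.target)
        part = pc.assign_partition(peps, n_folds=2, seed=15)
        cfg = TrainConfig(hidden_sizes=(10,), n_restarts=1, max_epochs=60, patience=10)
        model = pc.train_core_model(data, part, cfg, seed=16)
        report = pc.evaluate(model, data.subset(part.indices("test")))
        assert abs(report["scc"]) < 0.15

    def test_deterministic_given_seed(self, planted_motif):
        peps = pc.generate_peptide_library(800, seed=17)
        spec = pc.SyntheticArraySpec(n_peptides=800, noise_sd=0.1, seed=18)
        data = pc.median_and_normalize(pc.simulate_intensities(planted_motif, peps, spec))
        part = pc.assign_partition(peps, n_folds=2, seed=19)
        cfg = TrainConfig(hidden_sizes=(8,), n_restarts=1, max_epochs=30, patience=5)
        m1 = pc.train_core_model(data, part, cfg, seed=20)
        m2 = pc.train_core_model(data, part, cfg, seed=20)
        assert np.array_equal(m1.predict(peps[:50]), m2.predict(peps[:50]))

    def test_serialization_round_trip(self, trained_small_model, tmp_path):
        model, data, _ = trained_small_model
        model.save(tmp_path / "model.json")
        loaded = BindingModel.load(tmp_path / "model.json")
        assert loaded.max_median == model.max_median
        assert np.allclose(loaded.predict(data.peptides[:50]), model.predict(data.peptides[:50]))

    def test_anchor_substitution_raises_true_score(self, planted_motif):
        """Planting an anchor-preferred residue never lowers the latent score."""
        from pepchip.alphabet import AMINO_ACIDS
        from pepchip.synthetic import latent_scores

        ic = planted_motif.information_content()
        anchor_pos = int(np.argmax(ic))
        best_aa = AMINO_ACIDS[int(np.argmax(planted_motif.weights[anchor_pos]))]
        peps = pc.generate_peptide_library(200, seed=22)
        for pep in peps[:50]:
            # substitute into the first window at the anchor position
            improved = (
                pep[:anchor_pos] + best_aa + pep[anchor_pos + 1 :]
            )
            s0, s1 = latent_scores(planted_motif, [pep, improved])
            assert s1 >= s0 - 1e-9


class TestEvaluate:
    def test_identity_oracle_is_perfect(self, noiseless_dataset):
        class Identity:
            max_median = None

            def __init__(self, data):
                self.lookup = dict(zip(data.peptides, data.target))

            def predict(self, peptides):
                return np.array([self.lookup[p] for p in peptides])

        model = Identity(noiseless_dataset)
        model.max_median = noiseless_dataset.max_median
        report = pc.evaluate(model, noiseless_dataset)
        assert report["pcc"] == pytest.approx(1.0, abs=1e-9)
        assert report["scc"] == pytest.approx(1.0, abs=1e-9)

    def test_scc_invariant_under_back_transform(self, trained_small_model):
        from scipy.stats import spearmanr

        model, data, part = trained_small_model
        test = data.subset(part.indices("test"))
        preds = model.predict(test.peptides)
        scc_norm = spearmanr(preds, test.target)[0]
        report = pc.evaluate(model, test)
        assert report["scc"] == pytest.approx(scc_norm, abs=1e-9)

    def test_correlations_match_textbook_formulas(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0, 7.0, 3.0, 9.0, 6.0, 10.0]) / 10.0
        y = np.array([2.0, 3.0, 1.0, 7.0, 6.0, 8.0, 4.0, 10.0, 5.0, 9.0]) / 10.0

        class Fixed:
            max_median = 254.0

            def predict(self, peptides):
                return x

        data = pc.ArrayDataset(
            peptides=[f"ACDEFGHIKLMN{aa}" for aa in "ACDEFGHIKL"],
            replicates=np.repeat(y[:, None] * 254, 3, axis=1),
        )
        data = pc.median_and_normalize(data)
        report = pc.evaluate(Fixed(), data)
        xi = pc.back_transform(x, 254.0)
        yi = pc.back_transform(data.target, 254.0)
        assert report["pcc"] == pytest.approx(pearson_textbook(xi, yi), abs=1e-9)
        assert report["scc"] == pytest.approx(spearman_textbook(xi, yi), abs=1e-9)

    def test_degenerate_predictions_reported(self, noiseless_dataset):
        class Const:
            max_median = 254.0

            def predict(self, peptides):
                return np.full(len(peptides), 0.3)

        report = pc.evaluate(Const(), noiseless_dataset)
        assert report["pcc"] is None and "note" in report


class TestBootstrapCompare:
    def test_identical_models_give_half(self):
        rng = np.random.default_rng(0)
        t = rng.random(200)
        assert bootstrap_compare(t, t, t, n_boot=500, seed=1) == pytest.approx(0.5)

    def test_oracle_beats_noise_decisively(self):
        rng = np.random.default_rng(1)
        t = rng.random(1000)
        oracle = t + 0.01 * rng.standard_normal(1000)
        noise = rng.random(1000)
        p = bootstrap_compare(oracle, noise, t, n_boot=2000, seed=2)
        assert p <= 0.001

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        t, a, b = rng.random(100), rng.random(100), rng.random(100)
        p1 = bootstrap_compare(a, b, t, n_boot=1000, seed=4)
        p2 = bootstrap_compare(a, b, t, n_boot=1000, seed=4)
        assert p1 == p2

    def test_small_n_boot_rejected(self):
        t = np.arange(20.0)
        with pytest.raises(ValueError):
            bootstrap_compare(t, t, t, n_boot=50)
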