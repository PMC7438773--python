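"""Digestion, overlap exclusion, Frank statistics, and paired tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import wilcoxon

import pepchip as pc
from pepchip.alphabet import AMINO_ACIDS
from pepchip.benchmark import (
    benchmark_model,
    filter_best_frank,
    frank,
    mean_frank_random_scorer,
    summarize_and_test,
)

from _oracles import overlap_exclusion_bruteforce


class FixedScorer:
    """Maps given peptides to given scores; anything else scores 0."""

    def __init__(self, table):
        self.table = table

    def predict(self, peptides):
        return np.array([self.table.get(p, 0.0) for p in peptides])


class TestDigest:
    def test_window_count(self):
        d = pc.digest("A" * 20, 15)
        assert len(d.windows) == 6

    def test_window_equals_protein(self):
        d = pc.digest("ACDEFGHIKLMNPQR", 15)
        assert d.windows == ["ACDEFGHIKLMNPQR"]

    def test_enumeration(self):
        d = pc.digest("ABCDEFG", 3)
        assert d.windows == ["ABC", "BCD", "CDE", "DEF", "EFG"]

    def test_short_protein_rejected(self):
        with pytest.raises(ValueError):
            pc.digest("ACDEF", 15)


class TestExcludeOverlapping:
    def test_identical_candidate_excluded(self):
        assert pc.exclude_overlapping(["ACDEFGHIKLMNP"], ["ACDEFGHIKLMNP"]) == []

    def test_worked_overlap_pair_excluded(self):
        assert pc.exclude_overlapping(["AALITRGLTEMGR"], ["ARTALITRGLTEM"]) == []

    def test_unknown_residue_excluded(self):
        assert pc.exclude_overlapping(["ACDEFGHIKLMNX"], []) == []

    def test_short_overlap_kept(self):
        # only 8 shared contiguous residues
        assert pc.exclude_overlapping(["ACDEFGHIKLMNP"], ["CDEFGHIKWWWWW"]) == [
            "ACDEFGHIKLMNP"
        ]

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(0)
        cands = pc.generate_peptide_library(200, length=15, seed=1)
        refs = pc.generate_peptide_library(200, length=13, seed=2)
        # implant guaranteed hits
        for i in range(0, 200, 10):
            cands[i] = cands[i][:3] + refs[i][:9] + cands[i][12:]
        assert pc.exclude_overlapping(cands, refs) == overlap_exclusion_bruteforce(
            cands, refs
        )


class TestPredictVariableLength:
    def test_thirteen_mer_passthrough(self, oracle_model):
        pep = "ACDEFGHIKLMNP"
        got = pc.predict_variable_length(oracle_model, [pep])
        assert got[0] == pytest.approx(float(oracle_model.predict([pep])[0]))

    def test_nineteen_mer_window_count(self, oracle_model):
        pep = "ACDEFGHIKLMNPQRSTVW"
        subs = [pep[o : o + 13] for o in range(7)]
        expect = max(oracle_model.predict(subs))
        assert pc.predict_variable_length(oracle_model, [pep])[0] == pytest.approx(
            float(expect)
        )

    def test_matches_enumeration_oracle_on_fifteen_mers(self, oracle_model):
        peps = pc.generate_peptide_library(100, length=15, seed=3)
        got = pc.predict_variable_length(oracle_model, peps)
        for pep, g in zip(peps, got):
            subs = [pep[o : o + 13] for o in range(3)]
            assert g == pytest.approx(float(max(oracle_model.predict(subs))))

    def test_short_peptide_rejected(self, oracle_model):
        with pytest.raises(ValueError):
            pc.predict_variable_length(oracle_model, ["ACDEFGHIKL"])


class TestFrank:
    def test_top_scoring_ligand_has_frank_zero(self):
        protein = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
        ligand = protein[10:25]
        d = pc.digest(protein, 15)
        table = {w: 0.1 for sub in d.windows for w in [sub[o : o + 13] for o in range(3)]}
        for o in range(3):
            table[ligand[o : o + 13]] = 0.9
        res = pc.frank(ligand, protein, FixedScorer(table))
        assert res.frank == 0.0

    def test_fraction_formula(self):
        # 13-mer ligand: every window is its own single 13-mer, so scores
        # can be assigned per window without coupling through subsequences
        rng = np.random.default_rng(4)
        protein = "".join(rng.choice(list(AMINO_ACIDS), 22))
        d = pc.digest(protein, 13)  # 10 windows
        assert len(d.windows) == 10
        scores = [0.5] * 10
        scores[2], scores[7] = 0.9, 0.8  # exactly two windows strictly above
        table = dict(zip(d.windows, scores))
        res = pc.frank(d.windows[5], protein, FixedScorer(table))
        assert res.frank == pytest.approx(0.2)

    def test_random_scorer_baseline_near_half(self):
        mean = mean_frank_random_scorer(n_proteins=300, seed=5)
        assert 0.49 <= mean <= 0.51

    def test_invariant_under_monotone_transform(self, oracle_model, planted_motif):
        recs, table = pc.generate_benchmark_proteins(
            planted_motif, n_proteins=25, protein_length=120, ligand_length=15, seed=6
        )
        seqs = {r.id: str(r.seq) for r in recs}

        class Squashed:
            def predict(self, peptides):
                return 1.0 / (1.0 + np.exp(-8.0 * oracle_model.predict(peptides)))

        for row in table.itertuples(index=False):
            f1 = pc.frank(row.peptide, seqs[row.protein_id], oracle_model)
            f2 = pc.frank(row.peptide, seqs[row.protein_id], Squashed())
            assert f1.frank == pytest.approx(f2.frank)

    def test_missing_ligand_warns_or_raises(self, oracle_model):
        protein = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"
        with pytest.warns(UserWarning):
            pc.frank("WWWWWWWWWWWWW", protein, oracle_model)
        with pytest.raises(ValueError):
            pc.frank(
                "WWWWWWWWWWWWW", protein, oracle_model, missing_ligand="error"
            )


class TestFilterAndSummaries:
    @staticmethod
    def _results(franks_by_model):
        rows = []
        for model_id, franks in franks_by_model.items():
            for i, f in enumerate(franks):
                rows.append(
                    {
                        "ligand": f"lig{i}",
                        "protein_id": f"prot{i}",
                        "model_id": model_id,
                        "frank": f,
                    }
                )
        return pd.DataFrame(rows)

    def test_min_rule_retains(self):
        df = self._results({"a": [0.30], "b": [0.10]})
        assert len(filter_best_frank(df)) == 2

    def test_min_rule_drops(self):
        df = self._results({"a": [0.20], "b": [0.16]})
        assert len(filter_best_frank(df)) == 0

    def test_vacuous_threshold(self):
        df = self._results({"a": [0.9, 0.8], "b": [0.99, 0.7]})
        assert len(filter_best_frank(df, threshold=1.0)) == 4

    def test_identical_models_p_one(self):
        franks = list(np.linspace(0.0, 0.4, 20))
        out = summarize_and_test(self._results({"a": franks, "b": franks}))
        assert out["pairwise_wilcoxon_pratt"]["a vs b"] == 1.0

    def test_uniform_shift_strongly_significant(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(0.1, 0.4, 50)
        out = summarize_and_test(self._results({"a": base - 0.05, "b": base}))
        assert out["pairwise_wilcoxon_pratt"]["a vs b"] < 0.001
        assert out["per_model"]["a"]["mean_frank"] < out["per_model"]["b"]["mean_frank"]

    def test_pratt_differs_from_zero_dropping(self):
        """30% zero differences: Pratt's ranked-zero treatment changes the p-value."""
        d = np.array([0.0, 0.0, 0.0, 0.05, 0.05, 0.05, -0.02, 0.04, 0.06, -0.01])
        x = np.linspace(0.1, 0.5, 10)
        y = x - d
        p_pratt = wilcoxon(x, y, zero_method="pratt").pvalue
        p_wilcox = wilcoxon(x, y, zero_method="wilcox").pvalue
        assert p_pratt != p_wilcox
        out = summarize_and_test(self._results({"a": x, "b": y}))
        assert out["pairwise_wilcoxon_pratt"]["a vs b"] == pytest.approx(p_pratt)


class TestEndToEndBenchmark:
    def test_trained_model_ranks_implanted_ligands(self, trained_small_model, planted_motif):
        model, _, _ = trained_small_model
        recs, table = pc.generate_benchmark_proteins(
            planted_motif, n_proteins=30, protein_length=200, ligand_length=15, seed=8
        )
        seqs = {r.id: str(r.seq) for r in recs}
        results = benchmark_model(model, seqs, table, model_id="core")
        assert results["frank"].median() <= 0.05

    def test_flat_motif_control_near_random(self, hash_scorer, planted_motif):
        recs, table = pc.generate_benchmark_proteins(
            planted_motif, n_proteins=40, protein_length=200, ligand_length=15, seed=9
        )
        seqs = {r.id: str(r.seq) for r in recs}
        results = benchmark_model(hash_scorer, seqs, table, model_id="rand")
        assert 0.3 <= results["frank"].mean() <= 0.7
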