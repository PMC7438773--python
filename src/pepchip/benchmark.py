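"""Rank-based ligand/epitope benchmarking with the Frank statistic.

A known binder (eluted ligand or CD4+ epitope) is evaluated against the
in-silico digest of its source protein: all windows of the ligand's length
are scored by the model and the Frank value is the fraction of windows
with a strictly higher score.  A perfectly ranked ligand has Frank 0; a
random scorer gives about 0.5.  Variable-length peptides (13-19 residues)
are scored as the maximum over their 13-mer subsequences.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from .alphabet import is_standard

OVERLAP_K = 9
MIN_SCORING_LENGTH = 13
FRANK_FILTER_THRESHOLD = 0.15


@dataclass
class DigestedProtein:
    """All sliding windows of one protein at a fixed window length."""

    protein_id: str
    windows: list[str]
    offsets: np.ndarray
    scores: np.ndarray | None = None


@dataclass
class FrankResult:
    """Per-ligand rank statistic within its digested source protein."""

    ligand: str
    protein_id: str
    n_windows: int
    n_higher: int
    frank: float
    model_id: str = ""


def digest(protein: str, window: int, protein_id: str = "protein") -> DigestedProtein:
    """Enumerate all overlapping windows of the given length, step 1."""
    if window < 1:
        raise ValueError("window length must be positive")
    if len(protein) < window:
        raise ValueError(
            f"protein ({len(protein)} aa) shorter than the window ({window} aa)"
        )
    n = len(protein) - window + 1
    return DigestedProtein(
        protein_id=protein_id,
        windows=[protein[o : o + window] for o in range(n)],
        offsets=np.arange(n),
    )


def _kmer_set(sequences, k: int = OVERLAP_K) -> set[str]:
    out: set[str] = set()
    for s in sequences:
        for o in range(len(s) - k + 1):
            out.add(s[o : o + k])
    return out


def exclude_overlapping(
    candidates: list[str],
    references: list[str] | set[str],
    k: int = OVERLAP_K,
) -> list[str]:
    """Drop candidates overlapping any reference by >= k contiguous residues,
    and candidates containing a non-standard residue.

    Two sequences share a contiguous stretch of >= k residues iff they share
    some exact k-mer, so the reference set is indexed by its k-mers.
    """
    ref_kmers = _kmer_set(references, k)
    kept = []
    for c in candidates:
        if not is_standard(c):
            continue
        if any(c[o : o + k] in ref_kmers for o in range(len(c) - k + 1)):
            continue
        kept.append(c)
    return kept


def predict_variable_length(model, peptides: list[str]) -> np.ndarray:
    """Score 13-19-mers as the maximum over their 13-mer subsequences.

    All subsequences of all peptides are scored in one model call and
    reduced by group maximum.
    """
    subs: list[str] = []
    group: list[int] = []
    for i, p in enumerate(peptides):
        if len(p) < MIN_SCORING_LENGTH:
            raise ValueError(f"peptide {p!r} shorter than {MIN_SCORING_LENGTH} residues")
        for o in range(len(p) - MIN_SCORING_LENGTH + 1):
            subs.append(p[o : o + MIN_SCORING_LENGTH])
            group.append(i)
    scores = np.asarray(model.predict(subs), dtype=float)
    out = np.full(len(peptides), -np.inf)
    np.maximum.at(out, np.asarray(group), scores)
    return out


def frank(
    ligand: str,
    protein: str,
    model,
    protein_id: str = "protein",
    model_id: str = "",
    exclude_refs: list[str] | None = None,
    missing_ligand: str = "warn",
    precomputed: DigestedProtein | None = None,
) -> FrankResult:
    """Frank value of one ligand within its source protein.

    The protein is digested at the ligand's length; windows overlapping
    ``exclude_refs`` by >= 9 residues are removed (the ligand's own windows
    are always kept); every window is scored with max-over-13-mer
    semantics; the Frank value is the count of windows scoring strictly
    above the ligand divided by the total window count (ligand included).
    If the ligand occurs several times, the best-scoring occurrence defines
    its score.  A ligand absent from its protein is scored independently
    with a warning (``missing_ligand='warn'``) or raises (``'error'``).
    """
    if precomputed is not None and precomputed.scores is not None:
        dig = precomputed
        scores = dig.scores
    else:
        dig = digest(protein, len(ligand), protein_id)
        windows = dig.windows
        if exclude_refs:
            keep_set = set(exclude_overlapping(windows, exclude_refs))
            keep = [i for i, w in enumerate(windows) if w in keep_set or w == ligand]
            dig = DigestedProtein(protein_id, [windows[i] for i in keep], dig.offsets[keep])
        scores = predict_variable_length(model, dig.windows)
        dig.scores = scores

    occurrences = [i for i, w in enumerate(dig.windows) if w == ligand]
    if occurrences:
        ligand_score = max(scores[i] for i in occurrences)
    else:
        msg = f"ligand {ligand!r} not found in protein {protein_id}"
        if missing_ligand == "error":
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
        ligand_score = float(predict_variable_length(model, [ligand])[0])

    n_windows = len(dig.windows)
    n_higher = int(np.sum(scores > ligand_score))
    return FrankResult(
        ligand=ligand,
        protein_id=protein_id,
        n_windows=n_windows,
        n_higher=n_higher,
        frank=n_higher / n_windows,
        model_id=model_id,
    )


def benchmark_model(
    model,
    proteins: dict[str, str],
    positives: pd.DataFrame,
    model_id: str = "model",
    exclude_refs: list[str] | None = None,
) -> pd.DataFrame:
    """Frank values of every positive ligand under one model.

    ``positives`` needs columns peptide and protein_id; protein sequences
    are looked up in ``proteins``.
    """
    rows = []
    for rec in positives.itertuples(index=False):
        res = frank(
            rec.peptide,
            proteins[rec.protein_id],
            model,
            protein_id=rec.protein_id,
            model_id=model_id,
            exclude_refs=exclude_refs,
        )
        rows.append(
            {
                "ligand": res.ligand,
                "protein_id": res.protein_id,
                "model_id": res.model_id,
                "n_windows": res.n_windows,
                "n_higher": res.n_higher,
                "frank": res.frank,
            }
        )
    return pd.DataFrame(rows)


def filter_best_frank(
    results: pd.DataFrame, threshold: float = FRANK_FILTER_THRESHOLD
) -> pd.DataFrame:
    """Keep ligands whose best (minimum) Frank across models is <= threshold.

    Limits the effect of noise and false-positive annotations: a ligand no
    model can rank reasonably well is dropped from the comparison.
    """
    best = results.groupby(["ligand", "protein_id"])["frank"].transform("min")
    return results[best <= threshold].reset_index(drop=True)


def summarize_and_test(results: pd.DataFrame, bonferroni: bool = False) -> dict:
    """Per-model Frank summaries and pairwise Wilcoxon signed-rank tests.

    Ligands are paired across models; zero differences are handled with
    Pratt's method (zeros are ranked, then dropped from the signed sum).
    All-zero difference vectors give p = 1.  Raw pairwise p-values are
    reported; Bonferroni correction is opt-in.
    """
    models = sorted(results["model_id"].unique())
    wide = results.pivot_table(
        index=["ligand", "protein_id"], columns="model_id", values="frank"
    ).dropna()
    summary = {
        m: {
            "median_frank": float(results.loc[results.model_id == m, "frank"].median()),
            "mean_frank": float(results.loc[results.model_id == m, "frank"].mean()),
            "n": int((results.model_id == m).sum()),
        }
        for m in models
    }
    pvalues = {}
    n_pairs = max(1, len(models) * (len(models) - 1) // 2)
    for a, b in itertools.combinations(models, 2):
        diff = wide[a].to_numpy() - wide[b].to_numpy()
        if np.all(diff == 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(wide[a], wide[b], zero_method="pratt").pvalue)
        if bonferroni:
            p = min(1.0, p * n_pairs)
        pvalues[f"{a} vs {b}"] = p
    return {"per_model": summary, "pairwise_wilcoxon_pratt": pvalues}


def mean_frank_random_scorer(
    n_proteins: int = 500,
    protein_length: int = 200,
    window: int = 15,
    seed: int = 0,
    per_window: bool = True,
) -> float:
    """Mean Frank of an uninformative scorer — the random-prediction baseline.

    Each simulated protein's windows receive i.i.d. Uniform(0, 1) scores.
    With ``per_window=True`` every window is designated the ligand in turn
    and the franks are averaged, which is the exact expectation over the
    ligand designation and converges to (N-1)/(2N) for N windows; with
    ``per_window=False`` a single random window per protein is the ligand
    (noisier, same expectation).
    """
    rng = np.random.default_rng(seed)
    n = protein_length - window + 1
    if n < 1:
        raise ValueError("protein shorter than the window")
    means = []
    for _ in range(n_proteins):
        scores = rng.random(n)
        if per_window:
            order = np.argsort(np.argsort(scores))  # rank from below, 0-based
            franks = (n - 1 - order) / n
            means.append(franks.mean())
        else:
            lig = int(rng.integers(0, n))
            means.append(np.sum(scores > scores[lig]) / n)
    return float(np.mean(means))


# --------------------------------------------------------------------- I/O
def read_proteins_fasta(path) -> dict[str, str]:
    """Read source proteins from FASTA into an id -> sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_positives_csv(path) -> pd.DataFrame:
    """Read a positives table (peptide, protein_id[, allele]) from CSV."""
    df = pd.read_csv(path)
    if not {"peptide", "protein_id"}.issubset(df.columns):
        raise ValueError("positives CSV needs columns: peptide, protein_id")
    return df


def results_to_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")
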