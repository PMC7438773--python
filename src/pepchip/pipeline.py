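"""End-to-end reproducible runs: simulate -> process -> split -> train ->
motif -> benchmark, with a manifest tying every output to its config."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml
from Bio import SeqIO

from . import arrays, benchmark, motif_tools, partition as partition_mod, synthetic
from .model import TrainConfig, evaluate, train_core_model
from .motif import pssm_correlation, write_pssm

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.  Every stage seed derives from ``seed``."""

    seed: int
    # synthetic data
    n_peptides: int = 5000
    peptide_length: int = 13
    n_anchors: int = 4
    anchor_strength: float = 3.0
    noise_sd: float = 0.3
    # partition
    test_fraction: float = 0.10
    n_folds: int = 10
    # model
    hidden_sizes: tuple[int, ...] = (20, 40, 60)
    n_restarts: int = 10
    learning_rate: float = 1.0
    max_epochs: int = 300
    patience: int = 20
    encoding: str = "blosum"
    # motif extraction
    pool_size: int = 100_000
    motif_fraction: float = 0.01
    gibbs_iterations: int = 100
    # benchmark
    n_benchmark_proteins: int = 50
    protein_length: int = 200
    ligand_length: int = 15
    frank_filter: float = 0.15

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        if "hidden_sizes" in raw:
            raw = {**raw, "hidden_sizes": tuple(raw["hidden_sizes"])}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_sizes"] = list(d["hidden_sizes"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full workflow and write all artifacts plus a manifest.

    Rerunning with the same config reproduces byte-identical outputs
    (float formatting in all writers is fixed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    outputs: dict[str, dict] = {}

    def register(stage: str, path: Path) -> None:
        outputs[path.name] = {"stage": stage, "sha256": _sha256(path), "config": cfg_hash}

    # -- simulate ---------------------------------------------------------
    motif_true = synthetic.generate_motif(
        seed=config.seed, n_anchors=config.n_anchors, anchor_strength=config.anchor_strength
    )
    peptides = synthetic.generate_peptide_library(
        config.n_peptides, length=config.peptide_length, seed=config.seed + 1
    )
    spec = synthetic.SyntheticArraySpec(
        n_peptides=config.n_peptides,
        peptide_length=config.peptide_length,
        noise_sd=config.noise_sd,
        seed=config.seed + 2,
    )
    raw = synthetic.simulate_intensities(motif_true, peptides, spec)
    raw.to_tsv(out / "library.tsv")
    register("simulate", out / "library.tsv")
    write_pssm(motif_true, out / "motif_true.pssm")
    register("simulate", out / "motif_true.pssm")

    # -- process ----------------------------------------------------------
    data = arrays.median_and_normalize(raw)
    data.processed_to_tsv(out / "processed.tsv")
    register("process", out / "processed.tsv")
    stats = arrays.replicate_stats(data)
    arrays.write_stats(stats, out / "consistency.json")
    register("process", out / "consistency.json")

    # -- split ------------------------------------------------------------
    part = partition_mod.assign_partition(
        data.peptides,
        test_fraction=config.test_fraction,
        n_folds=config.n_folds,
        seed=config.seed + 3,
    )
    part.to_tsv(out / "partition.tsv")
    register("split", out / "partition.tsv")

    # -- train ------------------------------------------------------------
    tconf = TrainConfig(
        hidden_sizes=config.hidden_sizes,
        n_restarts=config.n_restarts,
        learning_rate=config.learning_rate,
        max_epochs=config.max_epochs,
        patience=config.patience,
        encoding=config.encoding,
    )
    model = train_core_model(data, part, tconf, seed=config.seed + 4)
    model.save(out / "model.json")
    register("train", out / "model.json")
    test_idx = part.indices("test")
    report = evaluate(model, data.subset(test_idx))
    (out / "evaluation.json").write_text(json.dumps(report, indent=2) + "\n")
    register("train", out / "evaluation.json")

    # -- motif ------------------------------------------------------------
    recovered = motif_tools.extract_motif(
        model,
        pool_size=config.pool_size,
        fraction=config.motif_fraction,
        n_iterations=config.gibbs_iterations,
        seed=config.seed + 5,
    )
    write_pssm(recovered, out / "motif_recovered.pssm")
    register("motif", out / "motif_recovered.pssm")
    motif_pcc = pssm_correlation(motif_true, recovered)

    # -- benchmark --------------------------------------------------------
    records, positives = synthetic.generate_benchmark_proteins(
        motif_true,
        n_proteins=config.n_benchmark_proteins,
        protein_length=config.protein_length,
        ligand_length=config.ligand_length,
        seed=config.seed + 6,
    )
    SeqIO.write(records, str(out / "proteins.fasta"), "fasta")
    register("benchmark", out / "proteins.fasta")
    positives.to_csv(out / "positives.csv", index=False)
    register("benchmark", out / "positives.csv")
    proteins = {rec.id: str(rec.seq) for rec in records}
    results = benchmark.benchmark_model(model, proteins, positives, model_id="core")
    benchmark.results_to_tsv(results, out / "frank_results.tsv")
    register("benchmark", out / "frank_results.tsv")
    retained = benchmark.filter_best_frank(results, config.frank_filter)
    summary = {
        "median_frank": float(results["frank"].median()),
        "mean_frank": float(results["frank"].mean()),
        "n_ligands": int(len(results)),
        "n_retained_at_filter": int(retained[["ligand", "protein_id"]].drop_duplicates().shape[0]),
        "motif_recovery_pcc": motif_pcc,
    }
    (out / "benchmark_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    register("benchmark", out / "benchmark_summary.json")

    manifest = {"config": config.to_dict(), "config_hash": cfg_hash, "outputs": outputs}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline run complete: %s", out)
    return out
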