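"""Array readout processing: medians, 0-1 normalization, consistency statistics.

The chip readout is a table of peptides with replicate intensities on a
0-254 scale.  Training targets are built by taking the per-peptide median
intensity x~ and mapping it to [0, 1] with log(x~ + 1) / log(max(x~) + 1);
model evaluation back-transforms predictions onto the intensity scale.
Replicate consistency is summarized by a regularized coefficient of
variation sd / (mean + 1) and by the combined three-way replicate
correlation R123 = sqrt(R12^2 + R13^2 + R23^2 - 2 R12 R13 R23).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import N_RESIDUES, encode_matrix

logger = logging.getLogger(__name__)

INTENSITY_CEILING = 254.0


@dataclass
class ArrayDataset:
    """Peptides with replicate intensities and (optionally) normalized targets.

    ``replicates`` is an (n, n_replicates) float array; missing replicate
    measurements (excluded spots) are NaN.  ``median`` and ``target`` are
    filled in by :func:`median_and_normalize`.
    """

    peptides: list[str]
    replicates: np.ndarray
    median: np.ndarray | None = None
    target: np.ndarray | None = None
    max_median: float | None = None

    def __post_init__(self) -> None:
        self.replicates = np.asarray(self.replicates, dtype=np.float64)
        if self.replicates.ndim != 2 or self.replicates.shape[0] != len(self.peptides):
            raise ValueError("replicates must be (n_peptides, n_replicates)")
        lengths = {len(p) for p in self.peptides}
        if len(lengths) > 1:
            raise ValueError("all peptides must have the same length")

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[1]

    def subset(self, mask: np.ndarray) -> "ArrayDataset":
        """Row-subset by boolean mask or index array."""
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else np.asarray(mask)
        return ArrayDataset(
            peptides=[self.peptides[i] for i in idx],
            replicates=self.replicates[idx],
            median=None if self.median is None else self.median[idx],
            target=None if self.target is None else self.target[idx],
            max_median=self.max_median,
        )

    # ---------------------------------------------------------------- I/O
    @classmethod
    def from_tsv(cls, path: str | Path) -> "ArrayDataset":
        """Read a raw readout TSV with columns peptide, rep1, rep2, ... (NA = missing)."""
        df = pd.read_csv(path, sep="\t")
        rep_cols = [c for c in df.columns if c.startswith("rep")]
        if not rep_cols:
            raise ValueError("no replicate columns (rep1, rep2, ...) found")
        return cls(peptides=df["peptide"].tolist(), replicates=df[rep_cols].to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        """Write peptide + replicate columns; NaN is written as an empty field."""
        cols = {"peptide": self.peptides}
        for j in range(self.n_replicates):
            cols[f"rep{j + 1}"] = self.replicates[:, j]
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6g")

    def processed_to_tsv(self, path: str | Path) -> None:
        if self.median is None or self.target is None:
            raise ValueError("dataset has not been normalized")
        pd.DataFrame(
            {"peptide": self.peptides, "median": self.median, "target": self.target}
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def median_and_normalize(raw: ArrayDataset) -> ArrayDataset:
    """Compute per-peptide medians and map them to [0, 1] training targets.

    The median is taken over the available (non-missing) replicates.  The
    target is ln(median + 1) / ln(max_median + 1), where max_median is the
    dataset-wide maximum: the strongest peptide maps to exactly 1 and a
    zero median maps to exactly 0.  The ratio of logarithms is base
    invariant.
    """
    with np.errstate(all="ignore"):
        med = np.nanmedian(raw.replicates, axis=1)
    if np.any(np.isnan(med)):
        raise ValueError("peptides with no replicate measurements cannot be normalized")
    max_median = float(med.max())
    if max_median <= 0:
        raise ValueError("all medians are zero; normalization undefined")
    target = np.log(med + 1.0) / math.log(max_median + 1.0)
    return replace(raw, median=med, target=target, max_median=max_median)


def back_transform(targets: np.ndarray | float, max_median: float) -> np.ndarray | float:
    """Invert the normalization: exp(t * ln(max_median + 1)) - 1."""
    t = np.asarray(targets, dtype=float)
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("targets must lie in [0, 1]")
    out = np.expm1(t * math.log(max_median + 1.0))
    return float(out) if np.isscalar(targets) else out


def coefficient_of_variation(replicates: np.ndarray, ddof: int = 1) -> np.ndarray | float:
    """Regularized CoV of replicate intensities: sd / (mean + 1).

    ``ddof=1`` (sample standard deviation) is the default; with triplicates
    the population/sample choice is material, so it is exposed.  Rows with
    fewer than two available replicates raise.
    """
    x = np.asarray(replicates, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    n_avail = np.sum(~np.isnan(x), axis=1)
    if np.any(n_avail < 2):
        raise ValueError("CoV requires at least two replicate measurements")
    sd = np.nanstd(x, axis=1, ddof=ddof)
    mean = np.nanmean(x, axis=1)
    cov = sd / (mean + 1.0)
    return float(cov[0]) if squeeze else cov


def mean_cov(data: ArrayDataset, ddof: int = 1) -> float:
    """Unweighted mean CoV over peptides with >= 2 available replicates."""
    n_avail = np.sum(~np.isnan(data.replicates), axis=1)
    usable = data.replicates[n_avail >= 2]
    if usable.shape[0] == 0:
        raise ValueError("no peptides with >= 2 replicates")
    return float(np.mean(coefficient_of_variation(usable, ddof=ddof)))


def combined_replicate_pcc(columns: np.ndarray) -> float:
    """Three-way replicate consistency R123 from the pairwise correlations.

    R123 = sqrt(R12^2 + R13^2 + R23^2 - 2 * R12 * R13 * R23), computed from
    the three pairwise Pearson correlations of the replicate columns.  Rows
    with any missing replicate are dropped.  The radicand is clamped at 0
    and the result at 1 to guard floating-point excursions; clamping is
    logged.
    """
    x = np.asarray(columns, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of replicate columns")
    x = x[~np.isnan(x).any(axis=1)]
    if x.shape[0] < 3:
        raise ValueError("need at least 3 complete replicate rows")
    if np.any(np.ptp(x, axis=0) == 0):
        raise ValueError("constant replicate column: correlation undefined")
    r12 = stats.pearsonr(x[:, 0], x[:, 1])[0]
    r13 = stats.pearsonr(x[:, 0], x[:, 2])[0]
    r23 = stats.pearsonr(x[:, 1], x[:, 2])[0]
    return combine_pairwise_pcc(r12, r13, r23)


def combine_pairwise_pcc(r12: float, r13: float, r23: float) -> float:
    """Apply the R123 combination formula to three pairwise correlations."""
    radicand = r12**2 + r13**2 + r23**2 - 2.0 * r12 * r13 * r23
    if radicand < 0:
        logger.warning("R123 radicand %.3g clamped to 0", radicand)
        radicand = 0.0
    r = math.sqrt(radicand)
    if r > 1.0:
        logger.warning("R123 value %.6g clamped to 1", r)
        r = 1.0
    return r


def replicate_stats(data: ArrayDataset, ddof: int = 1) -> dict:
    """Consistency report: mean CoV, pairwise PCCs, and combined R123."""
    x = data.replicates
    complete = x[~np.isnan(x).any(axis=1)]
    r12 = stats.pearsonr(complete[:, 0], complete[:, 1])[0]
    r13 = stats.pearsonr(complete[:, 0], complete[:, 2])[0]
    r23 = stats.pearsonr(complete[:, 1], complete[:, 2])[0]
    return {
        "mean_cov": mean_cov(data, ddof=ddof),
        "pairwise_pcc": {"r12": float(r12), "r13": float(r13), "r23": float(r23)},
        "combined_pcc": combined_replicate_pcc(complete),
        "n_peptides": len(data),
    }


def write_stats(stats_dict: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(stats_dict, indent=2) + "\n")


def top_fraction_composition(data: ArrayDataset, fraction: float) -> np.ndarray:
    """Amino-acid composition of the top-signal fraction of the library.

    Pools every residue of the ceil(fraction * n) peptides with the highest
    median intensity and returns the 20 residue frequencies (summing to 1).
    Ties at the cutoff are broken by lexicographic peptide order.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if data.median is None:
        data = median_and_normalize(data)
    n_top = math.ceil(fraction * len(data))
    if n_top < 1:
        raise ValueError("fraction selects no peptides")
    order = sorted(range(len(data)), key=lambda i: (-data.median[i], data.peptides[i]))
    top = [data.peptides[i] for i in order[:n_top]]
    idx = encode_matrix(top)
    counts = np.bincount(idx.ravel(), minlength=N_RESIDUES).astype(float)
    return counts / counts.sum()


def composition_correlation(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """Pearson correlation between two 20-vector residue compositions."""
    return float(stats.pearsonr(np.asarray(freq_a), np.asarray(freq_b))[0])


def library_composition(peptides: list[str]) -> np.ndarray:
    """Overall residue frequencies of a peptide list."""
    idx = encode_matrix(peptides)
    counts = np.bincount(idx.ravel(), minlength=N_RESIDUES).astype(float)
    return counts / counts.sum()
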