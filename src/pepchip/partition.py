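"""Redundancy-aware data splitting for the chip library.

Two peptides are considered similar when they share a contiguous stretch of
at least 9 residues, or when at least 11 residues appear in the same order
in both (longest common subsequence).  Similar peptides must never be
separated across the held-out test set and the cross-validation folds, so
peptides are grouped into connected components of the similarity graph and
whole clusters are assigned to subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .alphabet import encode_indices

SUBSTRING_THRESHOLD = 9
SUBSEQUENCE_THRESHOLD = 11


def longest_common_substring(p: str, q: str) -> int:
    """Length of the longest contiguous substring occurring in both peptides."""
    if not p or not q:
        raise ValueError("peptides must be non-empty")
    # standard DP over suffix-extension lengths
    prev = [0] * (len(q) + 1)
    best = 0
    for a in p:
        cur = [0] * (len(q) + 1)
        for j, b in enumerate(q, start=1):
            if a == b:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def in_order_common_count(p: str, q: str) -> int:
    """Number of residues shared in the same order: longest common subsequence."""
    if not p or not q:
        raise ValueError("peptides must be non-empty")
    prev = [0] * (len(q) + 1)
    for a in p:
        cur = [0]
        for j, b in enumerate(q, start=1):
            cur.append(prev[j - 1] + 1 if a == b else max(prev[j], cur[-1]))
        prev = cur
    return prev[-1]


def are_similar(
    p: str,
    q: str,
    substring_threshold: int = SUBSTRING_THRESHOLD,
    subsequence_threshold: int = SUBSEQUENCE_THRESHOLD,
) -> bool:
    """Similarity rule: shared >= 9-mer, or >= 11 residues in the same order."""
    return (
        longest_common_substring(p, q) >= substring_threshold
        or in_order_common_count(p, q) >= subsequence_threshold
    )


@njit(cache=True)
def _lcs_pairs(idx_mat, cand_i, cand_j, threshold):
    """LCS length >= threshold check for candidate index pairs (numba kernel)."""
    n_cand = cand_i.shape[0]
    L = idx_mat.shape[1]
    keep = np.zeros(n_cand, dtype=np.bool_)
    prev = np.zeros(L + 1, dtype=np.int64)
    cur = np.zeros(L + 1, dtype=np.int64)
    for c in range(n_cand):
        a = idx_mat[cand_i[c]]
        b = idx_mat[cand_j[c]]
        prev[:] = 0
        for i in range(L):
            cur[0] = 0
            for j in range(L):
                if a[i] == b[j]:
                    cur[j + 1] = prev[j] + 1
                elif prev[j + 1] >= cur[j]:
                    cur[j + 1] = prev[j + 1]
                else:
                    cur[j + 1] = cur[j]
            prev, cur = cur, prev
        if prev[L] >= threshold:
            keep[c] = True
    return keep


@njit(cache=True)
def _count_prefilter(counts, threshold):
    """Pairs whose residue-count overlap allows an LCS >= threshold.

    sum_a min(count_p[a], count_q[a]) bounds the LCS from above, so this is
    a sound (never-excluding) prefilter.
    """
    n, A = counts.shape
    out_i = []
    out_j = []
    for i in range(n):
        for j in range(i + 1, n):
            s = 0
            for a in range(A):
                ci = counts[i, a]
                cj = counts[j, a]
                s += ci if ci < cj else cj
            if s >= threshold:
                out_i.append(i)
                out_j.append(j)
    return np.array(out_i, dtype=np.int64), np.array(out_j, dtype=np.int64)


def _similarity_edges(peptides: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Edges of the similarity graph, via a 9-mer index plus an LCS scan."""
    n = len(peptides)
    edges_i: list[int] = []
    edges_j: list[int] = []

    # contiguous rule: two peptides share a >=9-mer iff they share some 9-mer
    kmer_index: dict[str, list[int]] = {}
    for i, p in enumerate(peptides):
        for o in range(len(p) - SUBSTRING_THRESHOLD + 1):
            kmer_index.setdefault(p[o : o + SUBSTRING_THRESHOLD], []).append(i)
    for members in kmer_index.values():
        uniq = sorted(set(members))
        for a in range(len(uniq)):
            for b in range(a + 1, len(uniq)):
                edges_i.append(uniq[a])
                edges_j.append(uniq[b])

    # in-order rule: residue-count prefilter, then exact LCS on candidates
    lengths = {len(p) for p in peptides}
    if len(lengths) == 1:
        idx_mat = np.vstack([encode_indices(p) for p in peptides])
        counts = np.zeros((n, 20), dtype=np.int64)
        for i in range(n):
            counts[i] = np.bincount(idx_mat[i], minlength=20)
        ci, cj = _count_prefilter(counts, SUBSEQUENCE_THRESHOLD)
        if ci.size:
            keep = _lcs_pairs(idx_mat, ci, cj, SUBSEQUENCE_THRESHOLD)
            edges_i.extend(ci[keep].tolist())
            edges_j.extend(cj[keep].tolist())
    else:
        # unequal lengths occur only outside the primary pipeline; fall back
        # to the plain pairwise rule
        for i in range(n):
            for j in range(i + 1, n):
                if in_order_common_count(peptides[i], peptides[j]) >= SUBSEQUENCE_THRESHOLD:
                    edges_i.append(i)
                    edges_j.append(j)
    return np.asarray(edges_i, dtype=np.int64), np.asarray(edges_j, dtype=np.int64)


def cluster_peptides(peptides: list[str]) -> np.ndarray:
    """Connected components of the similarity graph (transitive closure).

    If a~b and b~c, all three share a cluster even when a and c are not
    directly similar; this is the conservative grouping that can never
    split a similar pair across subsets.
    """
    if len(set(peptides)) != len(peptides):
        raise ValueError("peptides must be distinct")
    n = len(peptides)
    ei, ej = _similarity_edges(peptides)
    graph = coo_matrix((np.ones(ei.size), (ei, ej)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


@dataclass
class Partition:
    """Cluster-respecting assignment of peptides to test set and CV folds."""

    peptides: list[str]
    cluster_id: np.ndarray
    subset: list[str]
    test_fraction: float = 0.10
    n_folds: int = 10

    def indices(self, subset: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.subset) if s == subset], dtype=np.int64)

    @property
    def fold_names(self) -> list[str]:
        return [f"fold_{k + 1}" for k in range(self.n_folds)]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"peptide": self.peptides, "cluster_id": self.cluster_id, "subset": self.subset}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Partition":
        df = pd.read_csv(path, sep="\t")
        subset = df["subset"].tolist()
        folds = sorted({s for s in subset if s.startswith("fold_")})
        return cls(
            peptides=df["peptide"].tolist(),
            cluster_id=df["cluster_id"].to_numpy(),
            subset=subset,
            n_folds=len(folds),
        )


def assign_partition(
    peptides: list[str],
    clusters: np.ndarray | None = None,
    test_fraction: float = 0.10,
    n_folds: int = 10,
    seed: int = 0,
) -> Partition:
    """Assign whole clusters to a held-out test set and ``n_folds`` CV folds.

    Peptides are sorted before shuffling so the partition is stable under
    input order.  Clusters are shuffled with ``seed`` and assigned greedily
    to the test set until it reaches ``test_fraction`` of the data; the
    remaining clusters are dealt to the currently smallest fold.  Because
    clusters are atomic the test fraction is approximate.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    order = sorted(range(len(peptides)), key=lambda i: peptides[i])
    sorted_peps = [peptides[i] for i in order]
    if clusters is None:
        labels = cluster_peptides(sorted_peps)
    else:
        clusters = np.asarray(clusters)
        labels_by_pep = {peptides[i]: clusters[i] for i in range(len(peptides))}
        labels = np.array([labels_by_pep[p] for p in sorted_peps])

    rng = np.random.default_rng(seed)
    cluster_ids = np.unique(labels)
    members: dict[int, list[int]] = {int(c): [] for c in cluster_ids}
    for i, lab in enumerate(labels):
        members[int(lab)].append(i)
    shuffled = list(cluster_ids[rng.permutation(cluster_ids.size)])

    n = len(peptides)
    n_test_target = test_fraction * n
    subset = [""] * n
    test_size = 0
    k = 0
    while k < len(shuffled) and test_size < n_test_target:
        cid = int(shuffled[k])
        if len(members[cid]) > n_test_target:
            # clusters are atomic, so an oversized one inflates the test set
            warnings.warn(
                f"cluster {cid} ({len(members[cid])} peptides) exceeds the "
                f"test-set target of {n_test_target:.0f}",
                stacklevel=2,
            )
        for i in members[cid]:
            subset[i] = "test"
        test_size += len(members[cid])
        k += 1

    fold_sizes = np.zeros(n_folds, dtype=np.int64)
    for cid in shuffled[k:]:
        f = int(np.argmin(fold_sizes))
        for i in members[int(cid)]:
            subset[i] = f"fold_{f + 1}"
        fold_sizes[f] += len(members[int(cid)])

    # map back to the caller's peptide order
    inv = np.empty(n, dtype=np.int64)
    for sorted_pos, orig_pos in enumerate(order):
        inv[orig_pos] = sorted_pos
    return Partition(
        peptides=list(peptides),
        cluster_id=labels[inv],
        subset=[subset[inv[i]] for i in range(n)],
        test_fraction=test_fraction,
        n_folds=n_folds,
    )
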