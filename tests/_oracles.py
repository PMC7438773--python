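"""Independent brute-force reference implementations used only by tests.

These deliberately re-derive results with different algorithms/code paths
than the package (exhaustive enumeration, all-pairs scans) so agreement is
informative.
"""

from __future__ import annotations

import numpy as np
from numba import njit


def substr_set(s: str) -> set[str]:
    return {s[i:j] for i in range(len(s)) for j in range(i + 1, len(s) + 1)}


def lcs_substring_enumeration(p: str, q: str) -> int:
    """Longest common contiguous substring by exhaustive substring enumeration."""
    common = substr_set(p) & substr_set(q)
    return max((len(s) for s in common), default=0)


def lcs_subsequence_recursive(p: str, q: str) -> int:
    """Longest common subsequence by memoized recursion (textbook form)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0 or j == 0:
            return 0
        if p[i - 1] == q[j - 1]:
            return rec(i - 1, j - 1) + 1
        return max(rec(i - 1, j), rec(i, j - 1))

    return rec(len(p), len(q))


def lcs_subsequence_bruteforce(p: str, q: str) -> int:
    """LCS by enumerating all subsequences of p (exponential; tiny inputs only)."""
    from itertools import combinations

    def subseqs(s: str):
        for r in range(len(s), 0, -1):
            for comb in combinations(range(len(s)), r):
                yield "".join(s[i] for i in comb)

    q_subs = set()
    from itertools import combinations as comb2

    for r in range(len(q), 0, -1):
        for c in comb2(range(len(q)), r):
            q_subs.add("".join(q[i] for i in c))
    for s in subseqs(p):
        if s in q_subs:
            return len(s)
    return 0


def similar_oracle(p: str, q: str) -> bool:
    return lcs_substring_enumeration(p, q) >= 9 or lcs_subsequence_recursive(p, q) >= 11


def connected_components_bfs(peptides: list[str], adjacency: np.ndarray) -> list[set[int]]:
    """Plain BFS components from a boolean adjacency matrix."""
    n = len(peptides)
    seen = [False] * n
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        comp = set()
        stack = [start]
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.add(u)
            for v in range(n):
                if adjacency[u, v] and not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(comp)
    return comps


@njit(cache=True)
def _pair_similar(a, b, sub_thr, lcs_thr):
    L1, L2 = a.shape[0], b.shape[0]
    # longest common contiguous substring, full DP
    best = 0
    prev = np.zeros(L2 + 1, dtype=np.int64)
    cur = np.zeros(L2 + 1, dtype=np.int64)
    for i in range(L1):
        for j in range(L2):
            if a[i] == b[j]:
                cur[j + 1] = prev[j] + 1
                if cur[j + 1] > best:
                    best = cur[j + 1]
            else:
                cur[j + 1] = 0
        prev, cur = cur, prev
        cur[:] = 0
    if best >= sub_thr:
        return True
    # longest common subsequence, full DP
    prev[:] = 0
    for i in range(L1):
        cur[0] = 0
        for j in range(L2):
            if a[i] == b[j]:
                cur[j + 1] = prev[j] + 1
            elif prev[j + 1] >= cur[j]:
                cur[j + 1] = prev[j + 1]
            else:
                cur[j + 1] = cur[j]
        prev, cur = cur, prev
    return prev[L2] >= lcs_thr


@njit(cache=True)
def pairwise_similarity_matrix(idx_mat, sub_thr=9, lcs_thr=11):
    """All-pairs similarity by full double DP — the O(n^2) brute force."""
    n = idx_mat.shape[0]
    adj = np.zeros((n, n), dtype=np.bool_)
    for i in range(n):
        for j in range(i + 1, n):
            if _pair_similar(idx_mat[i], idx_mat[j], sub_thr, lcs_thr):
                adj[i, j] = True
                adj[j, i] = True
    return adj


@njit(cache=True)
def count_cross_subset_violations(idx_mat, subset_codes, sub_thr=9, lcs_thr=11):
    """Number of similar pairs assigned to different subsets (brute force)."""
    n = idx_mat.shape[0]
    bad = 0
    for i in range(n):
        for j in range(i + 1, n):
            if subset_codes[i] != subset_codes[j]:
                if _pair_similar(idx_mat[i], idx_mat[j], sub_thr, lcs_thr):
                    bad += 1
    return bad


def overlap_exclusion_bruteforce(candidates: list[str], references: list[str], k: int = 9):
    """O(n*m) substring scan: keep candidates sharing no >=k-mer with any reference."""
    kept = []
    for c in candidates:
        if any(ch not in "ACDEFGHIKLMNPQRSTVWY" for ch in c):
            continue
        hit = False
        for r in references:
            for o in range(len(c) - k + 1):
                if c[o : o + k] in r:
                    hit = True
                    break
            if hit:
                break
        if not hit:
            kept.append(c)
    return kept


def pearson_textbook(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = np.sqrt(n * np.sum(x**2) - np.sum(x) ** 2) * np.sqrt(
        n * np.sum(y**2) - np.sum(y) ** 2
    )
    return float(num / den)


def spearman_textbook(x, y) -> float:
    from scipy.stats import rankdata

    return pearson_textbook(rankdata(x), rankdata(y))
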