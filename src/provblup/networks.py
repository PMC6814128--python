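"""Comparison and structure of genetic-correlation matrices.

Two model variants produce two trait-by-trait genetic correlation
matrices; their agreement is quantified by a Mantel test (Pearson
correlation of the off-diagonal upper triangles, permutation p-value), and
trait modules are sought by weighted-modularity community detection on the
graph whose edge weights are ``|r_G|``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _as_corr_frame(M) -> pd.DataFrame:
    df = pd.DataFrame(M)
    if df.shape[0] != df.shape[1]:
        raise ValueError("correlation matrix must be square")
    return df


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel_test(M1, M2, n_perm: int = 999, seed: int = 0):
    """Mantel correlation between two trait-correlation matrices.

    The statistic is the Pearson correlation of the upper off-diagonal
    triangles; the p-value comes from jointly permuting rows and columns
    of ``M2`` (one-sided: permuted statistic >= observed), with the +1
    correction.  Matrices must share trait set and order.
    """
    A = _as_corr_frame(M1)
    B = _as_corr_frame(M2)
    if A.shape != B.shape:
        raise ValueError("matrices differ in dimension")
    if list(A.index) != list(B.index):
        raise ValueError("matrices must share trait labels and order")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    a = _upper(A.to_numpy())
    Bm = B.to_numpy()
    b = _upper(Bm)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate (constant) off-diagonal entries")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    k = A.shape[0]
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(k)
        bp = _upper(Bm[np.ix_(p, p)])
        if np.corrcoef(a, bp)[0, 1] >= r_obs - 1e-12:
            count += 1
    pval = (count + 1) / (n_perm + 1)
    return r_obs, pval


@dataclass
class ModulePartition:
    """Trait-to-module assignment with its weighted modularity score."""

    assignment: dict
    q_mod: float

    def modules(self) -> list:
        out = {}
        for t, m in self.assignment.items():
            out.setdefault(m, []).append(t)
        return [sorted(v) for _, v in sorted(out.items())]


def modularity_score(W: np.ndarray, labels: np.ndarray) -> float:
    """Newman weighted modularity of a partition of a weighted graph."""
    W = np.asarray(W, dtype=float)
    two_m = W.sum()
    if two_m <= 0:
        return 0.0
    k = W.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(((W - np.outer(k, k) / two_m) * same).sum() / two_m)


def detect_modules(M) -> ModulePartition:
    """Greedy agglomerative modularity maximisation on ``|r_G|`` weights.

    Starts from singleton modules and repeatedly merges the pair of
    modules with the largest modularity gain until no merge improves the
    score.  An all-zero off-diagonal matrix yields a single module with
    Q = 0.
    """
    df = _as_corr_frame(M)
    traits = list(df.index)
    if len(traits) < 3:
        raise ValueError("module detection needs at least 3 traits")
    W = np.abs(df.to_numpy().copy())
    np.fill_diagonal(W, 0.0)
    n = len(traits)
    if W.sum() == 0:
        return ModulePartition({t: 0 for t in traits}, 0.0)

    labels = np.arange(n)
    best_q = modularity_score(W, labels)
    improved = True
    while improved:
        improved = False
        mods = np.unique(labels)
        best_pair, best_gain = None, 1e-12
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                cand = labels.copy()
                cand[cand == mods[j]] = mods[i]
                q = modularity_score(W, cand)
                if q - best_q > best_gain:
                    best_gain = q - best_q
                    best_pair = (mods[i], mods[j])
        if best_pair is not None:
            labels[labels == best_pair[1]] = best_pair[0]
            best_q = modularity_score(W, labels)
            improved = True
    if best_q < 0:
        # a single module (Q = 0) beats any negative-score local optimum
        return ModulePartition({t: 0 for t in traits}, 0.0)
    # renumber modules in order of first appearance
    remap = {}
    for l in labels:
        remap.setdefault(l, len(remap))
    assignment = {t: remap[l] for t, l in zip(traits, labels)}
    return ModulePartition(assignment, best_q)
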