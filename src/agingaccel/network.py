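"""Cross-cancer aging-acceleration similarity network.

For each cancer pair, Kolmogorov-Smirnov statistics are computed for every
cross-cancer gene pair over the two cancers' module genes, separately in
aging-accelerated (acceleration > 0) and non-accelerated samples; the summed
absolute difference, normalized by ln(N1) + ln(N2), is the pair's similarity.
Edges are selected top-k or by a strict threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityScore",
    "NetworkEdgeSet",
    "ks_statistic",
    "split_by_acceleration",
    "cancer_pair_similarity",
    "build_network",
    "similarity_matrix",
    "NetworkError",
]


class NetworkError(ValueError):
    pass


def ks_statistic(sample_a, sample_b) -> float:
    """Supremum absolute difference of the two empirical CDFs."""
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise NetworkError("ks_statistic needs nonempty samples")
    support = np.concatenate([a, b])
    fa = np.searchsorted(a, support, side="right") / a.size
    fb = np.searchsorted(b, support, side="right") / b.size
    return float(np.abs(fa - fb).max())


def split_by_acceleration(acceleration: pd.Series) -> tuple[pd.Index, pd.Index]:
    """Partition pair ids into accelerated (> 0) and non-accelerated (<= 0)."""
    acc = acceleration
    return acc.index[acc > 0], acc.index[acc <= 0]


@dataclass(frozen=True)
class SimilarityScore:
    cancer_1: str
    cancer_2: str
    n1: int
    n2: int
    ks_acc_sum: float
    ks_non_sum: float
    similarity: float


def cancer_pair_similarity(
    expr_1: pd.DataFrame,
    expr_2: pd.DataFrame,
    split_1: tuple,
    split_2: tuple,
    name_1: str = "cancer_1",
    name_2: str = "cancer_2",
    normalizer: str = "log",
) -> SimilarityScore:
    """Accumulated |KS_accelerated - KS_non_accelerated| over the N1 x N2
    cross-cancer gene pairs, normalized by ln(N1) + ln(N2).

    ``expr_i`` holds the module genes of cancer i (samples x genes);
    ``split_i`` is the (accelerated ids, non-accelerated ids) partition of its
    samples. ``normalizer='pairs'`` divides by N1*N2 instead of the default
    log-size denominator.
    """
    n1, n2 = expr_1.shape[1], expr_2.shape[1]
    if n1 == 0 or n2 == 0:
        raise NetworkError("both modules must be nonempty")
    acc_1, non_1 = split_1
    acc_2, non_2 = split_2
    for side, ids_a, ids_b in (("accelerated", acc_1, acc_2), ("non-accelerated", non_1, non_2)):
        if len(ids_a) < 2 or len(ids_b) < 2:
            raise NetworkError(f"{side} split has < 2 samples in one cancer")
    if normalizer == "log":
        denom = np.log(n1) + np.log(n2)
        if denom <= 0:
            raise NetworkError("ln(N1) + ln(N2) is not positive (single-gene modules)")
    elif normalizer == "pairs":
        denom = float(n1 * n2)
    else:
        raise NetworkError(f"unknown normalizer {normalizer!r}")

    acc_cols_1 = [np.sort(expr_1.loc[acc_1, g].to_numpy(dtype=float)) for g in expr_1.columns]
    non_cols_1 = [np.sort(expr_1.loc[non_1, g].to_numpy(dtype=float)) for g in expr_1.columns]
    acc_cols_2 = [np.sort(expr_2.loc[acc_2, g].to_numpy(dtype=float)) for g in expr_2.columns]
    non_cols_2 = [np.sort(expr_2.loc[non_2, g].to_numpy(dtype=float)) for g in expr_2.columns]

    acc_terms, non_terms, diff_terms = [], [], []
    for i in range(n1):
        for j in range(n2):
            ks_acc = _ks_sorted(acc_cols_1[i], acc_cols_2[j])
            ks_non = _ks_sorted(non_cols_1[i], non_cols_2[j])
            acc_terms.append(ks_acc)
            non_terms.append(ks_non)
            diff_terms.append(abs(ks_acc - ks_non))
    # fsum: correctly rounded, hence independent of accumulation order — keeps
    # similarity(c1, c2) == similarity(c2, c1) exact
    ks_acc_sum = math.fsum(acc_terms)
    ks_non_sum = math.fsum(non_terms)
    total = math.fsum(diff_terms)
    return SimilarityScore(
        cancer_1=name_1,
        cancer_2=name_2,
        n1=n1,
        n2=n2,
        ks_acc_sum=ks_acc_sum,
        ks_non_sum=ks_non_sum,
        similarity=total / denom,
    )


def _ks_sorted(a: np.ndarray, b: np.ndarray) -> float:
    support = np.concatenate([a, b])
    fa = np.searchsorted(a, support, side="right") / a.size
    fb = np.searchsorted(b, support, side="right") / b.size
    return float(np.abs(fa - fb).max())


def similarity_matrix(scores: list[SimilarityScore]) -> pd.DataFrame:
    names = sorted({s.cancer_1 for s in scores} | {s.cancer_2 for s in scores})
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for s in scores:
        mat.loc[s.cancer_1, s.cancer_2] = s.similarity
        mat.loc[s.cancer_2, s.cancer_1] = s.similarity
    np.fill_diagonal(mat.to_numpy(), 0.0)
    return mat


@dataclass
class NetworkEdgeSet:
    mode: str  # "top_k" | "threshold"
    parameter: float
    edges: list[tuple[str, str, float]]  # (cancer_a, cancer_b, similarity)

    def degrees(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for a, b, _ in self.edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg


def build_network(scores: list[SimilarityScore], mode: str, parameter: float) -> NetworkEdgeSet:
    """Select edges: ``top_k`` takes the k highest similarities (boundary ties
    broken by lexicographic cancer-pair name); ``threshold`` keeps edges with
    similarity strictly greater than the cutoff."""
    if not scores:
        raise NetworkError("need at least one cancer pair")
    items = []
    for s in scores:
        a, b = sorted((s.cancer_1, s.cancer_2))
        items.append((a, b, s.similarity))
    if mode == "top_k":
        k = int(parameter)
        items.sort(key=lambda e: (-e[2], e[0], e[1]))
        edges = items[:k]
    elif mode == "threshold":
        edges = sorted(
            (e for e in items if e[2] > parameter), key=lambda e: (-e[2], e[0], e[1])
        )
    else:
        raise NetworkError(f"invalid mode {mode!r} (expected 'top_k' or 'threshold')")
    return NetworkEdgeSet(mode=mode, parameter=float(parameter), edges=edges)
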