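"""Aging-acceleration-associated mutation/expression sets and bipartite networks.

Per cancer, an L1-regularized regression of aging acceleration on the binary
mutation matrix (and, separately, on paired expression differences) selects
the acceleration-associated sets; Kruskal-Wallis tests between selected
mutations and selected expression deltas build the bipartite edge list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

from .clock import bh_fdr, kruskal_wallis

__all__ = [
    "LassoFit",
    "BipartiteEdge",
    "expression_delta",
    "lasso_select",
    "bipartite_network",
    "ModuleError",
    "MIN_MUTATED_SAMPLES",
]

#: Mutation predictors with fewer mutated samples than this are excluded.
MIN_MUTATED_SAMPLES = 3


class ModuleError(ValueError):
    pass


def expression_delta(tumor: pd.DataFrame, normal: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-pair tumor-minus-normal expression, one row per complete pair.

    ``tumor``/``normal`` are sample-indexed; pairing follows ``annotations``
    (columns ``pair_id`` and ``status``).
    """
    ann = annotations
    t_ann = ann[ann["status"] == "tumor"]
    n_ann = ann[ann["status"] == "normal"]
    t_pairs = set(t_ann["pair_id"])
    n_pairs = set(n_ann["pair_id"])
    unpaired = sorted(t_pairs.symmetric_difference(n_pairs))
    if unpaired:
        raise ModuleError(f"unpaired sample for pair id {unpaired[0]!r}")
    t = tumor.loc[t_ann.index].set_axis(t_ann["pair_id"].to_numpy(), axis=0)
    n = normal.loc[n_ann.index].set_axis(n_ann["pair_id"].to_numpy(), axis=0)
    n = n.loc[t.index]
    out = t - n
    out.index.name = "pair_id"
    return out


@dataclass
class LassoFit:
    """L1 path plus 5-fold CV diagnostics and the selected predictor set."""

    predictor_ids: list[str]
    lambdas: np.ndarray  # descending
    coefficients: np.ndarray  # (n_predictors, n_lambdas)
    mse_per_lambda: np.ndarray
    chosen_lambda: float
    selected_ids: list[str]
    coefficients_at_chosen: pd.Series = field(default=None)
    selection_rule: str = "1se"
    mse_se_at_min: float = 0.0


def lasso_select(
    x: pd.DataFrame,
    y,
    folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 100,
    eps: float = 1e-3,
    rule: str = "1se",
) -> LassoFit:
    """LASSO over a descending lambda grid with k-fold CV MSE model choice.

    ``rule='min'`` chooses the lambda minimizing mean CV MSE (largest lambda,
    i.e. sparsest model, among exact minimizers). The default ``rule='1se'``
    chooses the largest lambda whose CV MSE stays within one standard error of
    that minimum — the smallest-MSE model of minimal complexity. Coefficients
    come from a full-data path fit at the chosen lambda. Deterministic given
    ``seed`` (fold assignment).
    """
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ModuleError("X rows and y must align")
    if len(x) < folds:
        raise ModuleError(f"need at least folds={folds} rows")
    if np.std(y) == 0:
        warnings.warn("zero-variance response: returning empty selection", stacklevel=2)
        lam = np.array([1.0])
        return LassoFit(
            predictor_ids=list(x.columns),
            lambdas=lam,
            coefficients=np.zeros((x.shape[1], 1)),
            mse_per_lambda=np.array([0.0]),
            chosen_lambda=1.0,
            selected_ids=[],
            coefficients_at_chosen=pd.Series(0.0, index=x.columns),
        )
    xv = x.to_numpy(dtype=float)
    x_mean = xv.mean(axis=0)
    y_mean = y.mean()
    xc, yc = xv - x_mean, y - y_mean

    lambdas, coefs, _ = lasso_path(xc, yc, eps=eps, alphas=n_lambdas)

    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sq_err = np.zeros((len(y), len(lambdas)))
    fold_mse = np.zeros((folds, len(lambdas)))
    for f, (train, test) in enumerate(cv.split(xv)):
        xt_mean = xv[train].mean(axis=0)
        yt_mean = y[train].mean()
        _, fold_coefs, _ = lasso_path(
            xv[train] - xt_mean, y[train] - yt_mean, alphas=lambdas
        )
        pred = (xv[test] - xt_mean) @ fold_coefs + yt_mean
        sq_err[test] = (pred - y[test][:, None]) ** 2
        fold_mse[f] = sq_err[test].mean(axis=0)
    mse = sq_err.mean(axis=0)

    best = mse.min()
    min_idx = int(np.flatnonzero(mse == best)[0])  # lambdas descend: sparsest minimizer
    se = float(fold_mse[:, min_idx].std(ddof=1) / np.sqrt(folds))
    if rule == "min":
        chosen_idx = min_idx
    elif rule == "1se":
        chosen_idx = int(np.flatnonzero(mse <= best + se)[0])
    else:
        raise ModuleError(f"unknown selection rule {rule!r}")
    chosen = float(lambdas[chosen_idx])
    beta = coefs[:, chosen_idx]
    selected = [c for c, b in zip(x.columns, beta) if b != 0.0]
    return LassoFit(
        predictor_ids=list(x.columns),
        lambdas=lambdas,
        coefficients=coefs,
        mse_per_lambda=mse,
        chosen_lambda=chosen,
        selected_ids=selected,
        coefficients_at_chosen=pd.Series(beta, index=x.columns),
        selection_rule=rule,
        mse_se_at_min=se,
    )


def filter_mutation_predictors(mutations: pd.DataFrame, min_mutated: int = MIN_MUTATED_SAMPLES) -> pd.DataFrame:
    """Drop mutation columns observed in fewer than ``min_mutated`` samples."""
    counts = mutations.sum(axis=0)
    keep = counts >= min_mutated
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"excluding {dropped} mutation predictor(s) with < {min_mutated} mutated samples", stacklevel=2)
    return mutations.loc[:, keep]


@dataclass(frozen=True)
class BipartiteEdge:
    mutation_id: str
    expression_id: str
    p_value: float
    fdr: float


def bipartite_network(
    mutations: pd.DataFrame,
    deltas: pd.DataFrame,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.2,
) -> list[BipartiteEdge]:
    """Kruskal-Wallis edges between selected mutations and expression deltas.

    For every (mutation, gene) pair, the gene's delta values are split by the
    mutation's 0/1 status; BH FDR is computed over all tested pairs within the
    cancer; pairs with p < 0.05 and FDR < 0.2 are retained, sorted by p.
    """
    if mutations.shape[1] == 0 or deltas.shape[1] == 0:
        raise ModuleError("both the mutation and expression sets must be nonempty")
    if not mutations.index.equals(deltas.index):
        raise ModuleError("mutation and delta matrices must share sample ordering")
    pairs: list[tuple[str, str]] = []
    ps: list[float] = []
    for m in mutations.columns:
        status = mutations[m].to_numpy()
        carriers = status == 1
        if carriers.all() or not carriers.any():
            warnings.warn(f"mutation {m!r} has a degenerate status vector; pairs skipped", stacklevel=2)
            continue
        for g in deltas.columns:
            vals = deltas[g].to_numpy()
            _, p = kruskal_wallis([vals[~carriers], vals[carriers]])
            pairs.append((m, g))
            ps.append(p)
    if not pairs:
        return []
    fdrs = bh_fdr(np.clip(ps, np.finfo(float).tiny, 1.0))
    edges = [
        BipartiteEdge(m, g, float(p), float(f))
        for (m, g), p, f in zip(pairs, ps, fdrs)
        if p < p_threshold and f < fdr_threshold
    ]
    edges.sort(key=lambda e: (e.p_value, e.mutation_id, e.expression_id))
    return edges
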