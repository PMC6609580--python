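"""Information-theoretic eQTL module discovery.

For each acceleration-associated mutation: differential-expression candidates
(paired sign test + BH FDR + fold change), Kruskal-Wallis ranking against
mutation status, ternary discretization (mean +/- sd/2), greedy mRMR
re-ranking on mutual information, and leave-one-out CV to size the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .clock import bh_fdr, kruskal_wallis

__all__ = [
    "DegRecord",
    "EqtlModuleResult",
    "sign_test",
    "deg_candidates",
    "ternary_discretize",
    "mutual_information",
    "mrmr_rank",
    "loocv_size",
    "find_modules",
    "EqtlError",
]

#: LOOCV error at or above this marks a module as non-informative.
NON_INFORMATIVE_ERROR = 0.4


class EqtlError(ValueError):
    pass


def sign_test(paired_diffs) -> float:
    """Exact two-sided sign test on the count of positive differences.

    Zero differences are dropped; all-zero input yields p = 1.
    """
    d = np.asarray(paired_diffs, dtype=float)
    if d.size == 0:
        raise EqtlError("empty difference vector")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    k = int((d > 0).sum())
    lower = binom.cdf(k, n, 0.5)
    upper = binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass(frozen=True)
class DegRecord:
    gene_id: str
    p_value: float
    fdr: float
    fold_change: float
    retained: bool


def deg_candidates(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.2,
    fc_threshold: float = 2.0,
) -> tuple[list[str], list[DegRecord]]:
    """Differentially expressed candidates: per-gene sign test on paired
    differences, BH FDR over genes, and median per-pair tumor/normal fold
    change > 2 (or < 1/2). Rows of ``tumor`` and ``normal`` must align pairwise.
    """
    if tumor.shape != normal.shape:
        raise EqtlError("tumor and normal matrices must align pairwise")
    tv, nv = tumor.to_numpy(dtype=float), normal.to_numpy(dtype=float)
    diffs = tv - nv
    ps = np.array([sign_test(diffs[:, j]) for j in range(diffs.shape[1])])
    fdrs = bh_fdr(np.clip(ps, np.finfo(float).tiny, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(nv > 0, tv / nv, np.nan)
    n_bad = int(np.isnan(ratios).sum())
    if n_bad:
        warnings.warn(f"{n_bad} pair/gene ratio(s) skipped for nonpositive normal values", stacklevel=2)
    fcs = np.nanmedian(ratios, axis=0)
    records, kept = [], []
    for j, gene in enumerate(tumor.columns):
        fc = float(fcs[j])
        ok = (
            ps[j] < p_threshold
            and fdrs[j] < fdr_threshold
            and np.isfinite(fc)
            and (fc > fc_threshold or fc < 1.0 / fc_threshold)
        )
        records.append(DegRecord(gene, float(ps[j]), float(fdrs[j]), fc, ok))
        if ok:
            kept.append(gene)
    return kept, records


def ternary_discretize(values) -> np.ndarray:
    """Map to {-1, 0, 1} by mean +/- sd/2 thresholds (sample sd, strict
    inequalities; boundary values fall in the middle bin)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise EqtlError("need >= 2 values to discretize")
    sd = v.std(ddof=1)
    if sd == 0:
        return np.zeros(v.size, dtype=int)
    mean = v.mean()
    out = np.zeros(v.size, dtype=int)
    out[v > mean + sd / 2] = 1
    out[v < mean - sd / 2] = -1
    return out


def mutual_information(x, y) -> float:
    """Plug-in mutual information of two discrete vectors, in bits."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size:
        raise EqtlError("length mismatch")
    if x.size == 0:
        raise EqtlError("empty input")
    n = x.size
    xs, xi = np.unique(x, return_inverse=True)
    ys, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xs.size, ys.size))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    ratio = joint[nz] / (px[:, None] * py[None, :])[nz]
    return float(max(0.0, np.sum(joint[nz] * np.log2(ratio))))


def mrmr_rank(expr_discrete: pd.DataFrame, label, k: int | None = None) -> list[str]:
    """Greedy mRMR forward ranking: first gene maximizes relevance I(g; label);
    each subsequent gene maximizes relevance minus the mean mutual information
    against already-selected genes. Ties break by gene id.
    """
    label = np.asarray(label)
    if k is None:
        k = expr_discrete.shape[1]
    if k > expr_discrete.shape[1]:
        raise EqtlError("k exceeds the number of candidate genes")
    if k == 0:
        return []
    if len(set(label.tolist())) < 2:
        raise EqtlError("label must contain both classes")
    genes = list(expr_discrete.columns)
    cols = {g: expr_discrete[g].to_numpy() for g in genes}
    relevance = {g: mutual_information(cols[g], label) for g in genes}
    selected: list[str] = []
    remaining = set(genes)
    mi_cache: dict[tuple[str, str], float] = {}
    while len(selected) < k:
        best_gene, best_score = None, -np.inf
        for g in sorted(remaining):
            if selected:
                red = 0.0
                for s in selected:
                    key = (g, s)
                    if key not in mi_cache:
                        mi_cache[key] = mutual_information(cols[g], cols[s])
                    red += mi_cache[key]
                red /= len(selected)
            else:
                red = 0.0
            score = relevance[g] - red
            if score > best_score:
                best_gene, best_score = g, score
        selected.append(best_gene)
        remaining.discard(best_gene)
    return selected


def loocv_size(
    expr: pd.DataFrame,
    label,
    max_size: int | None = None,
    c: float = 1.0,
) -> tuple[np.ndarray, int]:
    """Leave-one-out misclassification of the mutation label from the top-s
    genes of an mRMR-ordered expression matrix, for s = 1..max_size; the module
    size is the smallest s attaining the minimum error."""
    label = np.asarray(label)
    n = len(label)
    classes, counts = np.unique(label, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise EqtlError("LOOCV needs >= 2 samples in each class")
    if max_size is None:
        max_size = expr.shape[1]
    if max_size > expr.shape[1]:
        raise EqtlError("max_size exceeds the number of genes")
    xv = expr.to_numpy(dtype=float)
    curve = np.empty(max_size)
    for s in range(1, max_size + 1):
        wrong = 0
        xs = xv[:, :s]
        for i in range(n):
            train = np.ones(n, dtype=bool)
            train[i] = False
            if len(set(label[train].tolist())) < 2:
                wrong += 1  # degenerate training fold counts as a miss
                continue
            clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=c))
            clf.fit(xs[train], label[train])
            wrong += int(clf.predict(xs[i : i + 1])[0] != label[i])
        curve[s - 1] = wrong / n
    size = int(np.argmin(curve)) + 1  # argmin takes the first (smallest) index
    return curve, size


@dataclass
class EqtlModuleResult:
    """Ranked differential-expression module for one mutation."""

    mutation_id: str
    mrmr_order: list[str]
    loocv_error_curve: np.ndarray
    module_size: int
    module_gene_ids: list[str]
    informative: bool
    deg_records: list[DegRecord] = field(default_factory=list, repr=False)


def find_modules(
    tumor_expr: pd.DataFrame,
    normal_expr: pd.DataFrame,
    mutation_status: pd.DataFrame,
    selected_mutations: list[str],
    min_mutated: int = 3,
    max_module_size: int = 20,
    max_candidates: int = 30,
    deg: tuple[list[str], list[DegRecord]] | None = None,
) -> list[EqtlModuleResult]:
    """Run the full module-discovery chain for each selected mutation.

    ``tumor_expr``/``normal_expr`` rows align pairwise; ``mutation_status``
    rows align with ``tumor_expr`` (one row per pair, 0/1 per mutation).
    Mutations with fewer than ``min_mutated`` mutated (or unmutated) pairs are
    skipped with a warning.
    """
    if deg is None:
        deg = deg_candidates(tumor_expr, normal_expr)
    candidates, records = deg
    results: list[EqtlModuleResult] = []
    for mut in selected_mutations:
        if mut not in mutation_status.columns:
            raise EqtlError(f"unknown mutation id {mut!r}")
        status = mutation_status[mut].to_numpy()
        n_mut = int(status.sum())
        if n_mut < min_mutated or (len(status) - n_mut) < min_mutated:
            warnings.warn(f"mutation {mut!r} skipped: < {min_mutated} samples in a class", stacklevel=2)
            continue
        if not candidates:
            continue
        deltas = tumor_expr[candidates].to_numpy() - normal_expr[candidates].to_numpy()
        # rank candidates by KW p-value of delta vs mutation status
        kw_ps = [
            kruskal_wallis([deltas[status == 0, j], deltas[status == 1, j]])[1]
            for j in range(len(candidates))
        ]
        order = sorted(range(len(candidates)), key=lambda j: (kw_ps[j], candidates[j]))
        ranked = [candidates[j] for j in order][:max_candidates]
        delta_df = pd.DataFrame(
            tumor_expr[ranked].to_numpy() - normal_expr[ranked].to_numpy(), columns=ranked
        )
        disc = pd.DataFrame(
            {g: ternary_discretize(delta_df[g].to_numpy()) for g in ranked}, columns=ranked
        )
        mrmr_order = mrmr_rank(disc, status)
        cap = min(max_module_size, len(mrmr_order))
        curve, size = loocv_size(delta_df[mrmr_order], status, max_size=cap)
        results.append(
            EqtlModuleResult(
                mutation_id=mut,
                mrmr_order=mrmr_order,
                loocv_error_curve=curve,
                module_size=size,
                module_gene_ids=mrmr_order[:size],
                informative=bool(curve.min() < NON_INFORMATIVE_ERROR),
                deg_records=records,
            )
        )
    return results
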