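"""Hypergeometric gene-set enrichment with BH FDR and cross-cancer correlation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .clock import bh_fdr

__all__ = [
    "GeneSetCollection",
    "EnrichmentRecord",
    "read_gmt",
    "hypergeom_upper",
    "enrich",
    "cancer_correlation",
    "EnrichmentError",
]


class EnrichmentError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets over a gene universe (default: union of set members)."""

    sets: dict[str, list[str]]
    universe: set[str]

    @property
    def universe_size(self) -> int:
        return len(self.universe)

    @classmethod
    def from_sets(cls, sets: dict[str, list[str]], universe: set[str] | None = None) -> "GeneSetCollection":
        clean: dict[str, list[str]] = {}
        for name, genes in sets.items():
            uniq = list(dict.fromkeys(genes))
            if not uniq:
                raise EnrichmentError(f"gene set {name!r} is empty")
            clean[name] = uniq
        if universe is None:
            universe = set().union(*map(set, clean.values()))
        else:
            for name, genes in clean.items():
                outside = set(genes) - universe
                if outside:
                    raise EnrichmentError(
                        f"gene set {name!r} contains genes outside the universe: {sorted(outside)[:3]}"
                    )
        return cls(sets=clean, universe=universe)


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file (name, description, member genes; tab-separated).

    Duplicate genes within a set are dropped with a warning; a line with fewer
    than three fields is an error reported with its line number.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    lines = path.read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise EnrichmentError(f"empty GMT file: {path}")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise EnrichmentError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        uniq = list(dict.fromkeys(genes))
        if len(uniq) < len(genes):
            warnings.warn(f"{path}:{lineno}: duplicate genes in set {name!r} deduplicated", stacklevel=2)
        sets[name] = uniq
    return GeneSetCollection.from_sets(sets, universe=universe)


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
    return path


def hypergeom_upper(n_universe: int, m_set: int, n_query: int, k_overlap: int) -> float:
    """Exact upper tail P(X >= k) of Hypergeometric(N, M, n), in log space.

    ``k_overlap`` = 0 returns 1 exactly.
    """
    n, m, q, k = n_universe, m_set, n_query, k_overlap
    if not (0 <= m <= n and 0 <= q <= n):
        raise EnrichmentError("inconsistent counts: need M, n <= N and all nonnegative")
    if not 0 <= k <= min(m, q):
        raise EnrichmentError("inconsistent counts: need 0 <= k <= min(M, n)")
    if k == 0:
        return 1.0
    ks = np.arange(k, min(m, q) + 1)
    log_terms = (
        _log_comb(m, ks)
        + _log_comb(n - m, q - ks)
        - _log_comb(n, q)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    set_size: int  # M
    query_size: int  # n (restricted to the universe)
    overlap: int  # k
    p_value: float
    fdr: float
    significant: bool


def enrich(
    module_genes: list[str],
    collection: GeneSetCollection,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.2,
) -> list[EnrichmentRecord]:
    """One hypergeometric record per set, BH FDR over the whole collection,
    significance at p < 0.05 and FDR < 0.2; sorted by ascending p."""
    if not module_genes:
        raise EnrichmentError("empty module")
    query = set(module_genes) & collection.universe
    if not query:
        raise EnrichmentError("module is disjoint from the gene-set universe")
    n = collection.universe_size
    names = list(collection.sets)
    ps, sizes, overlaps = [], [], []
    for name in names:
        members = set(collection.sets[name])
        k = len(query & members)
        ps.append(hypergeom_upper(n, len(members), len(query), k))
        sizes.append(len(members))
        overlaps.append(k)
    fdrs = bh_fdr(np.clip(ps, np.finfo(float).tiny, 1.0))
    records = [
        EnrichmentRecord(
            set_name=name,
            set_size=m,
            query_size=len(query),
            overlap=k,
            p_value=float(p),
            fdr=float(f),
            significant=bool(p < p_threshold and f < fdr_threshold),
        )
        for name, m, k, p, f in zip(names, sizes, overlaps, ps, fdrs)
    ]
    records.sort(key=lambda r: (r.p_value, r.set_name))
    return records


def cancer_correlation(fdr_table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between cancers of their (1 - FDR) profiles.

    ``fdr_table`` is cancer x set; missing entries (sets untested in a cancer)
    are imputed FDR = 1. Cancers with a zero-variance profile get NaN
    correlations (reported missing), diagonal stays 1.
    """
    if fdr_table.shape[0] < 2 or fdr_table.shape[1] < 2:
        raise EnrichmentError("need >= 2 cancers and >= 2 sets")
    filled = fdr_table.fillna(1.0)
    profiles = 1.0 - filled
    flat = profiles.std(axis=1, ddof=1) == 0
    if flat.any():
        warnings.warn(
            f"zero-variance (1-FDR) profile for: {list(profiles.index[flat])}; correlations undefined",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(profiles.to_numpy())
    corr[flat.to_numpy(), :] = np.nan
    corr[:, flat.to_numpy()] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=profiles.index, columns=profiles.index)
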