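"""Multi-tissue DNAm aging clock.

Screens age-associated CpGs on adjacent-normal methylation (Kruskal-Wallis on
binary age labels, Benjamini-Hochberg FDR), sizes the marker panel by
leave-one-tissue-out cross-validation of a linear epsilon-insensitive SVR,
scores samples (score > 0.5 means "old"), and tests tumor-vs-normal aging
acceleration.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "CandidateMarker",
    "ClockModel",
    "AgingScores",
    "age_label",
    "kruskal_wallis",
    "bh_fdr",
    "screen_markers",
    "train_clock",
    "score_samples",
    "balanced_error",
    "acceleration_test",
    "ClockError",
]

SCORE_THRESHOLD = 0.5
OLD_AGE_CUTOFF = 60.0


class ClockError(ValueError):
    pass


def age_label(age_years: float) -> int:
    """1 iff age is strictly greater than 60 years."""
    if age_years < 0:
        raise ClockError(f"negative age: {age_years}")
    return int(age_years > OLD_AGE_CUTOFF)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (midranks, tie-corrected) and chi-square upper-tail p.

    Degenerate input (all values identical across groups) returns (0, 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ClockError("need >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    n = len(pooled)
    if n < 3:
        raise ClockError("need total n >= 3")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)].sum()
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie == 0:
        return 0.0, 1.0
    h /= tie
    p = float(chi2.sf(h, len(groups) - 1))
    return float(h), p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ClockError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass(frozen=True)
class CandidateMarker:
    cpg_id: str
    p_value: float
    fdr: float


def screen_markers(
    dnam_normal: pd.DataFrame,
    labels,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.2,
) -> list[CandidateMarker]:
    """CpGs whose methylation differs between age groups: Kruskal-Wallis
    p < ``p_threshold`` and BH FDR < ``fdr_threshold``, sorted by ascending p
    (ties broken by CpG id)."""
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {0, 1}:
        raise ClockError("labels must contain both classes 0 and 1")
    vals = dnam_normal.to_numpy()
    mask = labels == 1
    ps = np.array(
        [kruskal_wallis([col[~mask], col[mask]])[1] for col in vals.T]
    )
    # KW returns exactly 1.0 for degenerate columns; keep within (0,1] for BH
    fdrs = bh_fdr(np.clip(ps, np.finfo(float).tiny, 1.0))
    hits = [
        CandidateMarker(cpg_id=c, p_value=float(p), fdr=float(f))
        for c, p, f in zip(dnam_normal.columns, ps, fdrs)
        if p < p_threshold and f < fdr_threshold
    ]
    hits.sort(key=lambda m: (m.p_value, m.cpg_id))
    return hits


@dataclass
class ClockModel:
    """Linear aging-score regressor over an ordered marker panel."""

    marker_ids: list[str]
    weights: np.ndarray
    offset: float
    score_threshold: float = SCORE_THRESHOLD
    learning_curve: list[tuple[int, float]] = dataclasses.field(default_factory=list)
    svr_c: float = 1.0
    svr_epsilon: float = 0.1

    def predict(self, dnam: pd.DataFrame) -> pd.Series:
        missing = [m for m in self.marker_ids if m not in dnam.columns]
        if missing:
            raise ClockError(f"missing marker column: {missing[0]!r}")
        x = dnam[self.marker_ids].to_numpy()
        return pd.Series(x @ self.weights + self.offset, index=dnam.index, name="score")

    def to_json(self) -> str:
        return json.dumps(
            {
                "marker_ids": self.marker_ids,
                "weights": list(map(float, self.weights)),
                "offset": float(self.offset),
                "score_threshold": self.score_threshold,
                "learning_curve": [[int(k), float(e)] for k, e in self.learning_curve],
                "svr_c": self.svr_c,
                "svr_epsilon": self.svr_epsilon,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClockModel":
        d = json.loads(text)
        d["weights"] = np.asarray(d["weights"], dtype=float)
        d["learning_curve"] = [(int(k), float(e)) for k, e in d["learning_curve"]]
        return cls(**d)


def _fit_svr(x: np.ndarray, y: np.ndarray, c: float, epsilon: float):
    model = make_pipeline(StandardScaler(), SVR(kernel="linear", C=c, epsilon=epsilon))
    model.fit(x, y)
    return model


def balanced_error(predicted, truth) -> float:
    """Mean of the false-negative and false-positive rates."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    pos = truth == 1
    neg = truth == 0
    if not pos.any() or not neg.any():
        raise ClockError("balanced error needs both truth classes")
    fnr = float((predicted[pos] != 1).mean())
    fpr = float((predicted[neg] != 0).mean())
    return (fnr + fpr) / 2.0


def train_clock(
    dnam_normal: pd.DataFrame,
    labels,
    tissues,
    candidates: list[str],
    k_grid: list[int] | None = None,
    c: float = 1.0,
    epsilon: float = 0.1,
) -> ClockModel:
    """Size the marker panel by leave-one-tissue-out CV and refit on all data.

    ``candidates`` must already be ordered (ascending screen p-value); for each
    panel size ``k`` in the grid the top-k candidates are used, the SVR is fit
    on all-but-one tissue, and the balanced classification error (score > 0.5)
    on the held-out tissue is averaged over tissues. The smallest ``k``
    attaining the minimum mean error wins.
    """
    if not candidates:
        raise ClockError("no candidate markers to train on")
    labels = np.asarray(labels)
    tissues = np.asarray(tissues)
    uniq = list(dict.fromkeys(tissues))
    if len(uniq) < 2:
        raise ClockError("need >= 2 training tissues for leave-one-tissue-out CV")
    if k_grid is None:
        k_grid = list(range(1, min(50, len(candidates)) + 1))
    x_all = dnam_normal[candidates].to_numpy()
    curve: list[tuple[int, float]] = []
    for k in k_grid:
        errs = []
        for tissue in uniq:
            test = tissues == tissue
            train = ~test
            if len(set(labels[test])) < 2 or len(set(labels[train])) < 2:
                warnings.warn(f"fold {tissue!r} skipped: a class is absent", stacklevel=2)
                continue
            model = _fit_svr(x_all[train][:, :k], labels[train], c, epsilon)
            pred = (model.predict(x_all[test][:, :k]) > SCORE_THRESHOLD).astype(int)
            errs.append(balanced_error(pred, labels[test]))
        if not errs:
            raise ClockError("every CV fold was degenerate")
        curve.append((k, float(np.mean(errs))))
    best_k = min(curve, key=lambda ke: (ke[1], ke[0]))[0]
    markers = candidates[:best_k]
    final = _fit_svr(x_all[:, :best_k], labels, c, epsilon)
    scaler: StandardScaler = final.named_steps["standardscaler"]
    svr: SVR = final.named_steps["svr"]
    w_std = svr.coef_.ravel()
    weights = w_std / scaler.scale_
    offset = float(svr.intercept_[0] - np.sum(w_std * scaler.mean_ / scaler.scale_))
    return ClockModel(
        marker_ids=list(markers),
        weights=weights,
        offset=offset,
        learning_curve=curve,
        svr_c=c,
        svr_epsilon=epsilon,
    )


@dataclass
class AgingScores:
    """Per-sample aging scores and labels; per-pair acceleration where pairs
    are complete (tumor score minus paired normal score)."""

    scores: pd.DataFrame  # index sample_id; columns score, label [, pair_id, status]
    acceleration: pd.Series  # index pair_id

    def accelerated_pairs(self) -> pd.Index:
        return self.acceleration.index[self.acceleration > 0]


def score_samples(model: ClockModel, dnam: pd.DataFrame, annotations: pd.DataFrame | None = None) -> AgingScores:
    """Apply the clock; unclipped linear scores, label 1 iff score > 0.5."""
    score = model.predict(dnam)
    frame = pd.DataFrame({"score": score, "label": (score > model.score_threshold).astype(int)})
    accel = pd.Series(dtype=float, name="acceleration")
    if annotations is not None:
        ann = annotations.loc[frame.index]
        frame["pair_id"] = ann["pair_id"]
        frame["status"] = ann["status"]
        tumor = frame[frame["status"] == "tumor"].set_index("pair_id")["score"]
        normal = frame[frame["status"] == "normal"].set_index("pair_id")["score"]
        common = tumor.index.intersection(normal.index)
        accel = (tumor.loc[common] - normal.loc[common]).rename("acceleration")
    return AgingScores(scores=frame, acceleration=accel)


def acceleration_test(tumor_scores, normal_scores) -> tuple[float, float, float, float]:
    """Two-group Kruskal-Wallis of tumor vs normal scores plus the median and
    mean score differences (tumor minus normal)."""
    tumor_scores = np.asarray(tumor_scores, dtype=float)
    normal_scores = np.asarray(normal_scores, dtype=float)
    if tumor_scores.size == 0 or normal_scores.size == 0:
        raise ClockError("acceleration test needs nonempty score vectors")
    h, p = kruskal_wallis([tumor_scores, normal_scores])
    return (
        h,
        p,
        float(np.median(tumor_scores) - np.median(normal_scores)),
        float(np.mean(tumor_scores) - np.mean(normal_scores)),
    )
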