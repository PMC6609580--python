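"""Data standardization.

DNA methylation is normalized per tissue by a three-step chain anchored on the
adjacent-normal samples: z-score against normal mean/sd, removal of the
projection onto the top principal directions of the normal matrix, then a
second z-score against the (detrended) normal mean/sd. Expression is scaled so
every sample shares the grand median of pre-scaling sample medians; mutation
counts are binarized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationState",
    "zscore_by_normal",
    "svd_detrend",
    "normalize_dnam",
    "median_normalize",
    "binarize_mutations",
    "preprocess_cohort",
    "ProcessedCohort",
    "PreprocessError",
]


class PreprocessError(ValueError):
    pass


@dataclass
class NormalizationState:
    """Audit record of a DNAm normalization run for one tissue."""

    normal_mean: pd.Series | None = None  # first z-score statistics
    normal_sd: pd.Series | None = None
    top_components: np.ndarray | None = None  # (n_components, n_features)
    final_mean: pd.Series | None = None  # second z-score statistics
    final_sd: pd.Series | None = None
    dropped_features: list[str] = field(default_factory=list)
    applied_steps: list[str] = field(default_factory=list)


def _check_features_match(tumor: pd.DataFrame, normal: pd.DataFrame) -> None:
    if not tumor.columns.equals(normal.columns):
        raise PreprocessError("tumor and normal matrices must share feature ids in order")


def zscore_by_normal(
    tumor: pd.DataFrame, normal: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, NormalizationState]:
    """Standardize both matrices featurewise by the normal mean and sample sd (ddof=1).

    Zero-variance features are dropped from both outputs with a warning.
    """
    _check_features_match(tumor, normal)
    if len(normal) < 2:
        raise PreprocessError("need >= 2 normal samples to estimate a standard deviation")
    mean = normal.mean(axis=0)
    sd = normal.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = list(sd.index[~keep])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance feature(s) at z-score step: {dropped[:5]}",
            stacklevel=2,
        )
    mean, sd = mean[keep], sd[keep]
    state = NormalizationState(
        normal_mean=mean, normal_sd=sd, dropped_features=dropped, applied_steps=["zscore"]
    )
    cols = sd.index
    return (
        (tumor[cols] - mean) / sd,
        (normal[cols] - mean) / sd,
        state,
    )


def svd_detrend(
    tumor: pd.DataFrame, normal: pd.DataFrame, n_components: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Subtract the projection of every sample onto the top ``n_components``
    principal directions of the normal matrix (shared basis for tumor rows).

    Returns the residual matrices and the (n_components, n_features) basis.
    """
    _check_features_match(tumor, normal)
    if n_components == 0:
        return tumor.copy(), normal.copy(), np.empty((0, tumor.shape[1]))
    cap = min(normal.shape)
    if n_components >= cap:
        raise PreprocessError(
            f"n_components={n_components} must be < min(normal matrix dims)={cap}"
        )
    _, _, vt = np.linalg.svd(normal.to_numpy(), full_matrices=False)
    basis = vt[:n_components]  # orthonormal rows
    detrend = lambda m: m - (m.to_numpy() @ basis.T) @ basis
    return detrend(tumor), detrend(normal), basis


def normalize_dnam(
    tumor: pd.DataFrame, normal: pd.DataFrame, n_components: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame, NormalizationState]:
    """z-score -> SVD detrend (top ``n_components`` of normal) -> z-score."""
    t1, n1, s1 = zscore_by_normal(tumor, normal)
    t2, n2, basis = svd_detrend(t1, n1, n_components)
    t3, n3, s3 = zscore_by_normal(t2, n2)
    state = NormalizationState(
        normal_mean=s1.normal_mean,
        normal_sd=s1.normal_sd,
        top_components=basis,
        final_mean=s3.normal_mean,
        final_sd=s3.normal_sd,
        dropped_features=s1.dropped_features + s3.dropped_features,
        applied_steps=["zscore", f"svd{n_components}", "zscore"],
    )
    return t3, n3, state


def median_normalize(expression: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so its median equals the grand median of the
    pre-scaling per-sample medians (midpoint convention for even counts)."""
    vals = expression.to_numpy()
    if (vals < 0).any():
        raise PreprocessError("expression values must be nonnegative")
    medians = np.median(vals, axis=1)
    zero = np.flatnonzero(medians == 0)
    if zero.size:
        raise PreprocessError(f"sample {expression.index[zero[0]]!r} has median 0")
    grand = float(np.median(medians))
    return expression.mul(grand / medians, axis=0)


def binarize_mutations(raw: pd.DataFrame) -> pd.DataFrame:
    """1 iff a gene carries at least one non-synonymous mutation call."""
    vals = raw.to_numpy()
    if (vals < 0).any():
        raise PreprocessError("mutation counts must be nonnegative")
    return (raw > 0).astype(np.int64)


@dataclass
class ProcessedCohort:
    """Cohort after standardization; DNAm is on the z scale, so it no longer
    obeys the raw-cohort [0, 1] invariant."""

    dnam: pd.DataFrame
    expression: pd.DataFrame
    mutation: pd.DataFrame
    annotations: pd.DataFrame
    states: dict[str, NormalizationState]

    def tumor_ids(self) -> pd.Index:
        return self.annotations.index[self.annotations["status"] == "tumor"]

    def normal_ids(self) -> pd.Index:
        return self.annotations.index[self.annotations["status"] == "normal"]

    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.annotations["tissue"]))


def preprocess_cohort(cohort, n_components: int = 3) -> ProcessedCohort:
    """Apply the full standardization to a :class:`~agingaccel.synth.PairedOmicsCohort`.

    DNAm normalization runs per tissue against that tissue's adjacent normals;
    features dropped in any tissue are dropped everywhere so the output matrix
    stays rectangular. Expression is median-normalized globally; mutations are
    binarized.
    """
    ann = cohort.annotations
    per_tissue: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    states: dict[str, NormalizationState] = {}
    for tissue in dict.fromkeys(ann["tissue"]):
        mask = ann["tissue"] == tissue
        t_ids = ann.index[mask & (ann["status"] == "tumor")]
        n_ids = ann.index[mask & (ann["status"] == "normal")]
        t_out, n_out, state = normalize_dnam(
            cohort.dnam.loc[t_ids], cohort.dnam.loc[n_ids], n_components
        )
        per_tissue[tissue] = (t_out, n_out)
        states[tissue] = state

    kept = None
    for t_out, _ in per_tissue.values():
        cols = set(t_out.columns)
        kept = cols if kept is None else kept & cols
    keep_cols = [c for c in cohort.dnam.columns if c in kept]
    pieces = []
    for t_out, n_out in per_tissue.values():
        pieces.append(t_out[keep_cols])
        pieces.append(n_out[keep_cols])
    dnam = pd.concat(pieces).loc[cohort.dnam.index]

    return ProcessedCohort(
        dnam=dnam,
        expression=median_normalize(cohort.expression),
        mutation=binarize_mutations(cohort.mutation),
        annotations=ann.copy(),
        states=states,
    )
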