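"""Synthetic paired tumor/normal multi-omics cohorts with planted ground truth.

Generates, for a configurable number of pseudo-tissues, paired tumor and
adjacent-normal samples with three aligned data channels:

* DNA methylation (beta values in [0, 1]) with a planted minority of
  age-associated CpGs,
* nonnegative linear-scale expression with planted driver-perturbed gene
  modules,
* a binary somatic-mutation matrix with planted driver mutations.

Driver mutations act through the methylation channel: a tumor carrying ``k``
drivers has its planted aging CpGs shifted further in the old-age direction,
so an elevated aging score (and hence aging acceleration) emerges through the
downstream clock rather than being injected post hoc.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "PairedOmicsCohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "synthetic_gene_sets",
    "CohortError",
]

#: Per-tumor Bernoulli rate of each planted driver mutation.
DRIVER_MUTATION_RATE = 0.3
#: Per-tumor Bernoulli rate of background (non-driver) mutations.
BACKGROUND_MUTATION_RATE = 0.05
#: Latent batch-like factors in the methylation channel. Their loadings are
#: scaled relative to noise_sd so they dominate the leading principal
#: components of the normal matrix — the structure the SVD detrending step is
#: meant to remove — while the planted age contrast stays outside the top
#: components.
N_BATCH_FACTORS = 3
BATCH_LOADING_SCALE = 0.4  # loading sd = BATCH_LOADING_SCALE * noise_sd

OLD_AGE_CUTOFF = 60.0


class CohortError(ValueError):
    """Raised for invalid configurations or malformed cohort directories."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator."""

    n_tissues: int = 11
    samples_per_tissue: int = 30  # tumor/normal pairs per tissue
    n_cpgs: int = 2000
    n_aging_cpgs: int = 20
    aging_effect: float = 0.3  # mean beta shift old vs young at aging CpGs
    n_genes: int = 1000
    n_mutation_genes: int = 300
    n_driver_mutations: int = 3
    driver_accel_effect: float = 0.5  # added aging acceleration per driver
    module_size: int = 6  # genes perturbed per driver
    module_effect: float = 2.0  # log2 fold change on perturbed genes
    noise_sd: float = 0.05
    age_range: tuple[float, float] = (30.0, 85.0)
    seed: int = 0
    #: log2-scale noise sd of the expression channel; defaults to noise_sd.
    #: Kept separate so expression signal-to-noise (which governs eQTL module
    #: sizing) can be tuned without touching the methylation channel.
    expr_noise_sd: float | None = None

    @property
    def expression_noise_sd(self) -> float:
        return self.noise_sd if self.expr_noise_sd is None else self.expr_noise_sd

    def validate(self) -> None:
        counts = {
            "n_tissues": self.n_tissues,
            "samples_per_tissue": self.samples_per_tissue,
            "n_cpgs": self.n_cpgs,
            "n_genes": self.n_genes,
            "n_mutation_genes": self.n_mutation_genes,
        }
        for name, value in counts.items():
            if value <= 0:
                raise CohortError(f"invariant violated: {name} must be positive (got {value})")
        for name in ("n_aging_cpgs", "n_driver_mutations", "module_size"):
            if getattr(self, name) < 0:
                raise CohortError(f"invariant violated: {name} must be nonnegative")
        if self.n_aging_cpgs > self.n_cpgs:
            raise CohortError("invariant violated: n_aging_cpgs <= n_cpgs")
        if self.n_driver_mutations > self.n_mutation_genes:
            raise CohortError("invariant violated: n_driver_mutations <= n_mutation_genes")
        if self.module_size * self.n_driver_mutations > self.n_genes:
            raise CohortError("invariant violated: module_size * n_driver_mutations <= n_genes")
        if not self.noise_sd > 0:
            raise CohortError("invariant violated: noise_sd > 0")
        if self.expr_noise_sd is not None and not self.expr_noise_sd > 0:
            raise CohortError("invariant violated: expr_noise_sd > 0")
        lo, hi = self.age_range
        if not lo < hi or lo < 0:
            raise CohortError("invariant violated: age_range must satisfy 0 <= min < max")


@dataclass
class GroundTruth:
    """Planted signal identities for downstream recovery tests."""

    aging_cpg_ids: list[str]
    driver_mutation_ids: list[str]
    module_map: dict[str, list[str]]  # driver id -> perturbed gene ids
    per_sample_acceleration: dict[str, float]  # pair id -> planted acceleration
    aging_cpg_directions: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


@dataclass
class PairedOmicsCohort:
    """Paired tumor/normal DNAm, expression and mutation matrices.

    All three matrices are samples x features DataFrames sharing one index
    (sample ids, same ordering); ``annotations`` carries sample_id (index),
    pair_id, tissue, age and status (``tumor``/``normal``).
    """

    dnam: pd.DataFrame
    expression: pd.DataFrame
    mutation: pd.DataFrame
    annotations: pd.DataFrame

    def validate(self, check_ranges: bool = True) -> None:
        idx = self.dnam.index
        for name, mat in (("expression", self.expression), ("mutation", self.mutation)):
            if not mat.index.equals(idx):
                bad = _first_mismatch(idx, mat.index)
                raise CohortError(f"sample ids of {name} disagree with dnam (first mismatch: {bad!r})")
        if not self.annotations.index.equals(idx):
            bad = _first_mismatch(idx, self.annotations.index)
            raise CohortError(f"annotation sample ids disagree with matrices (first mismatch: {bad!r})")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise CohortError(f"duplicate sample id {dup!r}")
        by_pair = self.annotations.groupby("pair_id")
        sizes = by_pair.size()
        if (sizes != 2).any():
            bad = sizes.index[sizes != 2][0]
            raise CohortError(f"pair {bad!r} does not occur exactly twice")
        statuses = by_pair["status"].agg(frozenset)
        if (statuses != frozenset({"tumor", "normal"})).any():
            bad = statuses.index[statuses != frozenset({"tumor", "normal"})][0]
            raise CohortError(f"pair {bad!r} lacks one tumor and one normal sample")
        if (by_pair["tissue"].nunique() != 1).any():
            raise CohortError("a pair spans two tissues")
        if check_ranges:
            vals = self.dnam.to_numpy()
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise CohortError("dnam values outside [0, 1]")
            mvals = self.mutation.to_numpy()
            if not np.isin(mvals, (0, 1)).all():
                raise CohortError("mutation values outside {0, 1}")

    def tumor_ids(self) -> pd.Index:
        return self.annotations.index[self.annotations["status"] == "tumor"]

    def normal_ids(self) -> pd.Index:
        return self.annotations.index[self.annotations["status"] == "normal"]

    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.annotations["tissue"]))

    def subset_tissue(self, tissue: str) -> "PairedOmicsCohort":
        keep = self.annotations.index[self.annotations["tissue"] == tissue]
        return PairedOmicsCohort(
            dnam=self.dnam.loc[keep],
            expression=self.expression.loc[keep],
            mutation=self.mutation.loc[keep],
            annotations=self.annotations.loc[keep],
        )

    def equals(self, other: "PairedOmicsCohort") -> bool:
        return (
            self.dnam.equals(other.dnam)
            and self.expression.equals(other.expression)
            and self.mutation.equals(other.mutation)
            and self.annotations.equals(other.annotations)
        )


def _first_mismatch(a: pd.Index, b: pd.Index):
    sa, sb = set(a), set(b)
    only = sorted(sa.symmetric_difference(sb))
    if only:
        return only[0]
    for x, y in zip(a, b):
        if x != y:
            return y
    return None


def generate_cohort(config: SyntheticConfig) -> tuple[PairedOmicsCohort, GroundTruth]:
    """Generate a paired cohort plus the ground truth of its planted signals.

    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    tissues = [f"T{i + 1:02d}" for i in range(config.n_tissues)]
    cpg_ids = [f"cg{i:05d}" for i in range(config.n_cpgs)]
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    mut_ids = [f"mut{i:04d}" for i in range(config.n_mutation_genes)]

    n_pairs = config.n_tissues * config.samples_per_tissue
    pair_tissue = np.repeat(tissues, config.samples_per_tissue)
    pair_ids = [f"{t}_p{i % config.samples_per_tissue:03d}" for i, t in enumerate(pair_tissue)]
    ages = rng.uniform(*config.age_range, size=n_pairs)

    # planted identities
    aging_idx = rng.choice(config.n_cpgs, size=config.n_aging_cpgs, replace=False)
    aging_idx.sort()
    directions = rng.choice([-1, 1], size=config.n_aging_cpgs)
    driver_idx = rng.choice(config.n_mutation_genes, size=config.n_driver_mutations, replace=False)
    driver_idx.sort()
    module_gene_idx = rng.choice(
        config.n_genes, size=config.module_size * config.n_driver_mutations, replace=False
    )
    module_map = {
        mut_ids[d]: sorted(gene_ids[g] for g in module_gene_idx[i * config.module_size : (i + 1) * config.module_size])
        for i, d in enumerate(driver_idx)
    }

    # mutation channel: drivers at an elevated rate in tumors, background rate
    # elsewhere; adjacent normals carry no somatic calls
    mut_tumor = (rng.random((n_pairs, config.n_mutation_genes)) < BACKGROUND_MUTATION_RATE).astype(np.int8)
    mut_tumor[:, driver_idx] = (
        rng.random((n_pairs, config.n_driver_mutations)) < DRIVER_MUTATION_RATE
    ).astype(np.int8)
    driver_count = mut_tumor[:, driver_idx].sum(axis=1) if config.n_driver_mutations else np.zeros(n_pairs)

    # methylation channel
    baseline = rng.uniform(0.2, 0.8, size=config.n_cpgs)
    old = (ages > OLD_AGE_CUTOFF).astype(float)
    base = np.tile(baseline, (n_pairs, 1))
    if config.n_aging_cpgs:
        age_shift = old[:, None] * directions[None, :] * config.aging_effect
        base_normal = base.copy()
        base_normal[:, aging_idx] += age_shift
        # tumors: extra shift in the old direction proportional to carried drivers
        tumor_shift = (
            directions[None, :]
            * config.aging_effect
            * config.driver_accel_effect
            * driver_count[:, None]
        )
        base_tumor = base.copy()
        base_tumor[:, aging_idx] += age_shift + tumor_shift
    else:
        base_normal = base
        base_tumor = base.copy()
    loadings = rng.normal(0, BATCH_LOADING_SCALE * config.noise_sd, (N_BATCH_FACTORS, config.n_cpgs))
    batch_normal = rng.normal(0, 1, (n_pairs, N_BATCH_FACTORS)) @ loadings
    batch_tumor = rng.normal(0, 1, (n_pairs, N_BATCH_FACTORS)) @ loadings
    dnam_normal = np.clip(
        base_normal + batch_normal + rng.normal(0, config.noise_sd, base.shape), 0.0, 1.0
    )
    dnam_tumor = np.clip(
        base_tumor + batch_tumor + rng.normal(0, config.noise_sd, base.shape), 0.0, 1.0
    )

    # expression channel: multiplicative log-normal noise around per-gene
    # baselines. Module genes are differentially expressed in every tumor
    # (baseline shift of module_effect log2FC, so they pass a paired
    # tumor-vs-normal DEG filter) and shifted by a further module_effect in
    # tumors carrying the owning driver (so mutation status stays
    # discriminable from the expression deltas).
    expr_base = rng.uniform(2.0, 10.0, size=config.n_genes)
    e_sd = config.expression_noise_sd
    log2_normal = np.log2(expr_base)[None, :] + rng.normal(0, e_sd, (n_pairs, config.n_genes))
    log2_tumor = np.log2(expr_base)[None, :] + rng.normal(0, e_sd, (n_pairs, config.n_genes))
    log2_tumor[:, module_gene_idx] += config.module_effect
    for i, d in enumerate(driver_idx):
        carriers = mut_tumor[:, d] == 1
        genes = module_gene_idx[i * config.module_size : (i + 1) * config.module_size]
        log2_tumor[np.ix_(carriers, genes)] += config.module_effect
    expr_normal = np.power(2.0, log2_normal)
    expr_tumor = np.power(2.0, log2_tumor)

    # interleave tumor/normal rows per pair, tumor first
    sample_ids, rows_dnam, rows_expr, rows_mut, ann_rows = [], [], [], [], []
    for i in range(n_pairs):
        for status, dn, ex, mu in (
            ("tumor", dnam_tumor[i], expr_tumor[i], mut_tumor[i]),
            ("normal", dnam_normal[i], expr_normal[i], np.zeros(config.n_mutation_genes, dtype=np.int8)),
        ):
            sample_ids.append(f"{pair_ids[i]}_{'T' if status == 'tumor' else 'N'}")
            rows_dnam.append(dn)
            rows_expr.append(ex)
            rows_mut.append(mu)
            ann_rows.append((pair_ids[i], pair_tissue[i], float(ages[i]), status))

    index = pd.Index(sample_ids, name="sample_id")
    cohort = PairedOmicsCohort(
        dnam=pd.DataFrame(np.asarray(rows_dnam), index=index, columns=cpg_ids),
        expression=pd.DataFrame(np.asarray(rows_expr), index=index, columns=gene_ids),
        mutation=pd.DataFrame(np.asarray(rows_mut, dtype=np.int64), index=index, columns=mut_ids),
        annotations=pd.DataFrame(ann_rows, index=index, columns=["pair_id", "tissue", "age", "status"]),
    )
    truth = GroundTruth(
        aging_cpg_ids=[cpg_ids[i] for i in aging_idx],
        driver_mutation_ids=[mut_ids[i] for i in driver_idx],
        module_map=module_map,
        per_sample_acceleration={
            pair_ids[i]: float(config.driver_accel_effect * driver_count[i]) for i in range(n_pairs)
        },
        aging_cpg_directions={cpg_ids[i]: int(d) for i, d in zip(aging_idx, directions)},
    )
    cohort.validate()
    return cohort, truth


_FILES = {
    "dnam": "dnam.tsv",
    "expression": "expression.tsv",
    "mutation": "mutation.tsv",
    "annotations": "annotations.tsv",
}


def write_cohort(cohort: PairedOmicsCohort, directory: str | Path, truth: GroundTruth | None = None) -> list[Path]:
    """Write the cohort directory layout (TSV matrices + annotations + optional truth)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for attr, fname in _FILES.items():
        path = directory / fname
        # %.17g + round_trip parsing keeps the TSV round trip bitwise lossless
        getattr(cohort, attr).to_csv(path, sep="\t", float_format="%.17g")
        written.append(path)
    if truth is not None:
        path = directory / "ground_truth.json"
        path.write_text(truth.to_json())
        written.append(path)
    return written


def read_cohort(directory: str | Path, check_ranges: bool = True) -> PairedOmicsCohort:
    """Read a cohort directory; raises :class:`CohortError` naming any missing file
    or the first sample id that disagrees between matrices and annotations."""
    directory = Path(directory)
    frames = {}
    for attr, fname in _FILES.items():
        path = directory / fname
        if not path.exists():
            raise CohortError(f"missing cohort file: {path}")
        frames[attr] = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    cohort = PairedOmicsCohort(**frames)
    cohort.validate(check_ranges=check_ranges)
    return cohort


def read_ground_truth(directory: str | Path) -> GroundTruth:
    path = Path(directory) / "ground_truth.json"
    if not path.exists():
        raise CohortError(f"missing cohort file: {path}")
    return GroundTruth.from_json(path.read_text())


def synthetic_gene_sets(
    truth: GroundTruth,
    all_genes: list[str],
    n_random_sets: int = 20,
    set_size: int = 15,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Gene-set collection for enrichment tests: one set per planted module
    (padded with random genes to ``set_size``) plus random background sets."""
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    pool = np.asarray(all_genes)
    for driver, genes in truth.module_map.items():
        pad = [g for g in rng.choice(pool, size=set_size, replace=False) if g not in genes]
        sets[f"planted_{driver}"] = sorted(set(genes) | set(pad[: max(0, set_size - len(genes))]))
    for i in range(n_random_sets):
        sets[f"random_{i:03d}"] = sorted(rng.choice(pool, size=set_size, replace=False))
    return sets
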