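"""End-to-end orchestration: simulate -> preprocess -> clock -> modules ->
eQTL -> enrichment -> cross-cancer network, with one root seed and a JSON run
manifest."""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clock import (
    ClockModel,
    acceleration_test,
    age_label,
    score_samples,
    screen_markers,
    train_clock,
)
from .enrichment import GeneSetCollection, cancer_correlation, enrich, read_gmt
from .eqtl import EqtlModuleResult, deg_candidates, find_modules
from .modules import (
    bipartite_network,
    expression_delta,
    filter_mutation_predictors,
    lasso_select,
)
from .network import (
    build_network,
    cancer_pair_similarity,
    similarity_matrix,
    split_by_acceleration,
)
from .preprocess import ProcessedCohort, preprocess_cohort
from .synth import (
    PairedOmicsCohort,
    SyntheticConfig,
    generate_cohort,
    read_cohort,
    read_ground_truth,
    synthetic_gene_sets,
    write_cohort,
)

__all__ = ["PipelineConfig", "run_all", "PipelineError"]


class PipelineError(RuntimeError):
    pass


@dataclass
class Thresholds:
    p: float = 0.05
    fdr: float = 0.2
    fold_change: float = 2.0
    score: float = 0.5

    def validate(self) -> None:
        for name, v in dataclasses.asdict(self).items():
            if v <= 0:
                raise PipelineError(f"threshold {name} must be positive")


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    input_dir: str | None = None  # existing cohort directory; else synthetic
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    thresholds: Thresholds = field(default_factory=Thresholds)
    gmt: str | None = None  # gene-set file; synthesized from ground truth if absent
    clock_max_k: int = 50
    lasso_folds: int = 5
    network_top_k: int = 10
    network_cutoff: float = 100.0
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate",
            "preprocess",
            "clock",
            "modules",
            "eqtl",
            "enrichment",
            "network",
        ]
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        cfg = cls(**{**raw, "thresholds": thresholds})
        cfg.thresholds.validate()
        return cfg


def _stage_seed(root: int, index: int) -> int:
    return int(np.random.SeedSequence([root, index]).generate_state(1)[0])


def run_all(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest.

    A stage failure raises :class:`PipelineError` naming the stage and cause.
    Reruns with identical config and seed reproduce all output files bitwise
    (the manifest's wall-time entries excepted).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "versions": {"agingaccel": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "stages": [],
    }
    state: dict = {}
    runners = {
        "simulate": _run_simulate,
        "preprocess": _run_preprocess,
        "clock": _run_clock,
        "modules": _run_modules,
        "eqtl": _run_eqtl,
        "enrichment": _run_enrichment,
        "network": _run_network,
    }
    for i, stage in enumerate(config.stages):
        if stage not in runners:
            raise PipelineError(f"unknown stage {stage!r}")
        t0 = time.perf_counter()
        try:
            outputs = runners[stage](config, state, out, _stage_seed(config.seed, i))
        except Exception as exc:  # halt with stage name and cause
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append(
            {
                "stage": stage,
                "seed": _stage_seed(config.seed, i),
                "outputs": [str(p) for p in outputs],
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# --- stages -----------------------------------------------------------------


def _run_simulate(config: PipelineConfig, state: dict, out: Path, seed: int) -> list[Path]:
    if config.input_dir is not None:
        path = Path(config.input_dir)
        if not path.exists():
            raise FileNotFoundError(f"input cohort directory not found: {path}")
        state["cohort"] = read_cohort(path)
        try:
            state["truth"] = read_ground_truth(path)
        except Exception:
            state["truth"] = None
        return []
    synth_cfg = SyntheticConfig(**{**config.synthetic, "seed": config.synthetic.get("seed", seed)})
    cohort, truth = generate_cohort(synth_cfg)
    state["cohort"], state["truth"] = cohort, truth
    return write_cohort(cohort, out / "cohort", truth)


def _run_preprocess(config: PipelineConfig, state: dict, out: Path, seed: int) -> list[Path]:
    if "cohort" not in state:
        path = Path(config.input_dir or out / "cohort")
        if not path.exists():
            raise FileNotFoundError(f"input cohort directory not found: {path}")
        state["cohort"] = read_cohort(path)
    processed = preprocess_cohort(state["cohort"])
    state["processed"] = processed
    pdir = out / "processed"
    pdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in (
        ("dnam", processed.dnam),
        ("expression", processed.expression),
        ("mutation", processed.mutation),
        ("annotations", processed.annotations),
    ):
        path = pdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t")
        written.append(path)
    return written


def _run_clock(config: PipelineConfig, state: dict, out: Path, seed: int) -> list[Path]:
    processed: ProcessedCohort = state["processed"]
    ann = processed.annotations
    normal_ids = processed.normal_ids()
    dnam_normal = processed.dnam.loc[normal_ids]
    labels = np.array([age_label(a) for a in ann.loc[normal_ids, "age"]])
    tissues = ann.loc[normal_ids, "tissue"].to_numpy()
    thr = config.thresholds
    candidates = screen_markers(dnam_normal, labels, thr.p, thr.fdr)
    if not candidates:
        raise PipelineError("marker screen returned no candidates")
    model = train_clock(
        dnam_normal,
        labels,
        tissues,
        [c.cpg_id for c in candidates],
        k_grid=list(range(1, min(config.clock_max_k, len(candidates)) + 1)),
    )
    scores = score_samples(model, processed.dnam, ann)
    h, p, med, mean = acceleration_test(
        scores.scores.loc[processed.tumor_ids(), "score"].to_numpy(),
        scores.scores.loc[normal_ids, "score"].to_numpy(),
    )
    state.update(model=model, scores=scores, candidates=candidates)
    written = []
    path = out / "clock_model.json"
    path.write_text(model.to_json())
    written.append(path)
    path = out / "markers.tsv"
    pd.DataFrame(
        [(c.cpg_id, c.p_value, c.fdr) for c in candidates],
        columns=["cpg_id", "p_value", "fdr"],
    ).to_csv(path, sep="\t", index=False)
    written.append(path)
    path = out / "scores.tsv"
    frame = scores.scores.copy()
    frame["acceleration"] = frame["pair_id"].map(scores.acceleration)
    frame.to_csv(path, sep="\t")
    written.append(path)
    path = out / "acceleration_test.json"
    path.write_text(json.dumps({"H": h, "p": p, "median_diff": med, "mean_diff": mean}, indent=2))
    written.append(path)
    return written


def _run_modules(config: PipelineConfig, state: dict, out: Path, seed: int) -> list[Path]:
    processed: ProcessedCohort = state["processed"]
    scores = state["scores"]
    ann = processed.annotations
    thr = config.thresholds
    mdir = out / "modules"
    mdir.mkdir(parents=True, exist_ok=True)
    written = []
    per_tissue: dict[str, dict] = {}
    for tissue in processed.tissues():
        mask = ann["tissue"] == tissue
        tumor_ids = ann.index[mask & (ann["status"] == "tumor")]
        pair_ids = ann.loc[tumor_ids, "pair_id"]
        accel = scores.acceleration.loc[pair_ids].to_numpy()
        mut = filter_mutation_predictors(processed.mutation.loc[tumor_ids])
        deltas = expression_delta(
            processed.expression.loc[ann.index[mask]],
            processed.expression.loc[ann.index[mask]],
            ann.loc[ann.index[mask]],
        ).loc[pair_ids]
        entry: dict = {"tumor_ids": tumor_ids, "pair_ids": pair_ids, "deltas": deltas}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mut_fit = lasso_select(mut, accel, folds=config.lasso_folds, seed=seed) if mut.shape[1] else None
            expr_fit = lasso_select(deltas, accel, folds=config.lasso_folds, seed=seed)
        entry["mutation_fit"], entry["expression_fit"] = mut_fit, expr_fit
        sel_mut = mut_fit.selected_ids if mut_fit else []
        sel_expr = expr_fit.selected_ids
        edges = []
        if sel_mut and sel_expr:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                edges = bipartite_network(
                    processed.mutation.loc[tumor_ids, sel_mut].set_axis(pair_ids, axis=0),
                    deltas[sel_expr],
                    thr.p,
                    thr.fdr,
                )
        entry["edges"] = edges
        per_tissue[tissue] = entry
        for label, fit in (("mutation", mut_fit), ("expression", expr_fit)):
            if fit is None:
                continue
            path = mdir / f"{tissue}_{label}_set.tsv"
            pd.DataFrame(
                {"id": fit.selected_ids, "coefficient": fit.coefficients_at_chosen[fit.selected_ids]}
            ).to_csv(path, sep="\t", index=False)
            written.append(path)
        path = mdir / f"{tissue}_edges.tsv"
        pd.DataFrame(
            [(e.mutation_id, e.expression_id, e.p_value, e.fdr) for e in edges],
            columns=["mutation", "gene", "p", "fdr"],
        ).to_csv(path, sep="\t", index=False)
        written.append(path)
    state["per_tissue"] = per_tissue
    return written


def _run_eqtl(config: PipelineConfig, state: dict, out: Path, seed: int) -> list[Path]:
    processed: ProcessedCohort = state["processed"]
    ann = processed.annotations
    edir = out / "eqtl"
    edir.mkdir(parents=True, exist_ok=True)
    written = []
    for tissue, entry in state["per_tissue"].items():
        tumor_ids = entry["tumor_ids"]
        pair_ids = entry["pair_ids"]
        normal_ids = ann.index[(ann["tissue"] == tissue) & (ann["status"] == "normal")]
        n_by_pair = ann.loc[normal_ids].reset_index().set_index("pair_id")["sample_id"]
        tumor_expr = processed.expression.loc[tumor_ids].set_axis(pair_ids, axis=0)
        normal_expr = processed.expression.loc[n_by_pair.loc[pair_ids]].set_axis(pair_ids, axis=0)
        status = processed.mutation.loc[tumor_ids].set_axis(pair_ids, axis=0)
        selected = entry["mutation_fit"].selected_ids if entry["mutation_fit"] else []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = find_modules(tumor_expr, normal_expr, status, selected)
        entry["eqtl_results"] = results
        rows = []
        for res in results:
            for rank, gene in enumerate(res.mrmr_order, start=1):
                rows.append(
                    (
                        res.mutation_id,
                        rank,
                        gene,
                        int(rank <= res.module_size),
                        float(res.loocv_error_curve[min(rank, len(res.loocv_error_curve)) - 1]),
                    )
                )
        path = edir / f"{tissue}_modules.tsv"
        pd.DataFrame(rows, columns=["mutation_id", "rank", "gene_id", "in_module", "loocv_error"]).to_csv(
            path, sep="\t", index=False
        )
        written.append(path)
        path = edir / f"{tissue}_curves.json"
        path.write_text(
            json.dumps(
                {
                    r.mutation_id: {
                        "curve": [float(e) for e in r.loocv_error_curve],
                        "module_size": r.module_size,
                        "module_gene_ids": r.module_gene_ids,
                        "informative": r.informative,
                    }
                    for r in results
                },
                indent=2,
            )
        )
        written.append(path)
    return written


def _tissue_module_genes(entry: dict) -> list[str]:
    genes: list[str] = []
    for res in entry.get("eqtl_results", []):
        genes.extend(res.module_gene_ids)
    return sorted(set(genes))


def _run_enrichment(config: PipelineConfig, state: dict, out: Path, seed: int) -> list[Path]:
    processed: ProcessedCohort = state["processed"]
    if config.gmt is not None:
        collection = read_gmt(config.gmt)
    else:
        truth = state.get("truth")
        if truth is None:
            raise PipelineError("no GMT file configured and no ground truth to synthesize one")
        sets = synthetic_gene_sets(truth, list(processed.expression.columns), seed=seed)
        collection = GeneSetCollection.from_sets(sets)
    thr = config.thresholds
    fdr_rows: dict[str, dict[str, float]] = {}
    written = []
    gdir = out / "enrichment"
    gdir.mkdir(parents=True, exist_ok=True)
    for tissue, entry in state["per_tissue"].items():
        genes = [g for g in _tissue_module_genes(entry) if g in collection.universe]
        if not genes:
            continue
        records = enrich(genes, collection, thr.p, thr.fdr)
        fdr_rows[tissue] = {r.set_name: r.fdr for r in records}
        path = gdir / f"{tissue}_enrichment.tsv"
        pd.DataFrame(
            [
                (r.set_name, r.set_size, r.query_size, r.overlap, r.p_value, r.fdr, int(r.significant))
                for r in records
            ],
            columns=["set", "M", "n", "k", "p", "fdr", "significant"],
        ).to_csv(path, sep="\t", index=False)
        written.append(path)
    if len(fdr_rows) >= 2:
        table = pd.DataFrame(fdr_rows).T.sort_index()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = cancer_correlation(table)
        path = gdir / "one_minus_fdr.tsv"
        (1.0 - table.fillna(1.0)).to_csv(path, sep="\t")
        written.append(path)
        path = gdir / "cancer_correlation.tsv"
        corr.to_csv(path, sep="\t")
        written.append(path)
    state["fdr_rows"] = fdr_rows
    return written


def _run_network(config: PipelineConfig, state: dict, out: Path, seed: int) -> list[Path]:
    processed: ProcessedCohort = state["processed"]
    scores = state["scores"]
    ann = processed.annotations
    modules: dict[str, list[str]] = {}
    splits: dict[str, tuple] = {}
    exprs: dict[str, pd.DataFrame] = {}
    for tissue, entry in state["per_tissue"].items():
        genes = _tissue_module_genes(entry)
        if len(genes) < 2:
            continue
        tumor_ids = entry["tumor_ids"]
        pair_ids = entry["pair_ids"]
        accel = scores.acceleration.loc[pair_ids]
        acc, non = split_by_acceleration(accel)
        if len(acc) < 2 or len(non) < 2:
            continue
        pair_to_tumor = ann.loc[tumor_ids].reset_index().set_index("pair_id")["sample_id"]
        expr = processed.expression.loc[tumor_ids, genes].set_axis(pair_ids, axis=0)
        modules[tissue], splits[tissue], exprs[tissue] = genes, (acc, non), expr
    sims = []
    names = sorted(modules)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sims.append(
                cancer_pair_similarity(exprs[a], exprs[b], splits[a], splits[b], a, b)
            )
    written = []
    ndir = out / "network"
    ndir.mkdir(parents=True, exist_ok=True)
    if sims:
        mat = similarity_matrix(sims)
        path = ndir / "similarity.tsv"
        mat.to_csv(path, sep="\t")
        written.append(path)
        for mode, parameter, fname in (
            ("top_k", config.network_top_k, "edges_topk.tsv"),
            ("threshold", config.network_cutoff, "edges_threshold.tsv"),
        ):
            edge_set = build_network(sims, mode, parameter)
            path = ndir / fname
            pd.DataFrame(edge_set.edges, columns=["cancer_a", "cancer_b", "similarity"]).to_csv(
                path, sep="\t", index=False
            )
            written.append(path)
            path = ndir / fname.replace(".tsv", ".json")
            path.write_text(
                json.dumps(
                    {
                        "mode": edge_set.mode,
                        "parameter": edge_set.parameter,
                        "nodes": sorted({n for e in edge_set.edges for n in e[:2]}),
                        "edges": [[a, b, s] for a, b, s in edge_set.edges],
                        "degrees": edge_set.degrees(),
                    },
                    indent=2,
                )
            )
            written.append(path)
    state["similarities"] = sims
    return written
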