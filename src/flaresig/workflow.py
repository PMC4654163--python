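"""One-command orchestration of the full analysis.

Stages, in fixed order: simulate-or-ingest -> normalise -> batch-correct ->
differential expression -> Venn partition -> PCA -> enrichment. Every stage
logs one structured line, persists its artifacts as TSV (plots as PNG) into
the run directory, and any failure aborts with the stage named. Reruns from
the persisted config snapshot are byte-identical under the same seed.

Config schema (YAML)
--------------------
seed: int                      # overrides sim.seed when simulating
simulate: bool
sim: {SimConfig overrides}     # when simulate true
counts: path; meta: path       # when simulate false (counts_format: tsv|rcc_dir)
normalization: {sd_multiplier: 2.0, pooling: pooled, pseudocount: 1.0}
batch: {mode: anchor|covariate|none}
de: {contrasts: [...], fold_threshold: 2.0, enfp_k: 4, enfp_m: null, alpha: null}
pca: {top: 20, components: [1, 2]}
enrichment: {gmt: path|null, fold_threshold: 1.5, alpha: 0.05}
outdir: path
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import batch as batch_mod
from . import diffexp, enrichment as enrich_mod, pca as pca_mod
from .io import (CountMatrix, GeneSetCollection, SampleTable, read_counts,
                 read_gene_sets, read_meta, write_table)
from .normalization import (ExpressionMatrix, FilterParams, apply_quantile,
                            normalize_pipeline)
from .simulate import SimulatedStudy, config_from_dict, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["ResultBundle", "run_full_analysis", "WorkflowError"]


class WorkflowError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class ResultBundle:
    expr: ExpressionMatrix
    de_tables: dict[str, pd.DataFrame]
    partition: dict[str, set[str]]
    pca: pca_mod.PCAResult
    top_genes: pd.DataFrame
    enrichment: pd.DataFrame | None
    provenance: list[dict]
    config: dict
    outdir: Path
    manifest: dict[str, str] = field(default_factory=dict)
    study: SimulatedStudy | None = None


_DEFAULTS: dict = {
    "seed": 0,
    "simulate": True,
    "sim": {},
    "counts": None,
    "counts_format": "tsv",
    "meta": None,
    "normalization": {"sd_multiplier": 2.0, "pooling": "pooled",
                      "pseudocount": 1.0},
    "batch": {"mode": "anchor"},
    "de": {"contrasts": None, "fold_threshold": 2.0, "enfp_k": 4,
           "enfp_m": None, "alpha": None},
    "pca": {"top": 20, "components": [1, 2]},
    "enrichment": {"gmt": None, "fold_threshold": 1.5, "alpha": 0.05},
    "outdir": "flaresig_run",
}


def _merge_config(raw: dict) -> dict:
    cfg = {}
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise WorkflowError(f"stage config: unknown key(s) {sorted(unknown)}")
    for key, default in _DEFAULTS.items():
        val = raw.get(key, default)
        if isinstance(default, dict) and val is not None:
            sub_unknown = set(val) - set(default) if default else set()
            if sub_unknown and key != "sim":
                raise WorkflowError(
                    f"stage config: unknown key(s) under {key!r}: "
                    f"{sorted(sub_unknown)}")
            merged = dict(default)
            merged.update(val)
            cfg[key] = merged
        else:
            cfg[key] = val
    if cfg["batch"]["mode"] not in ("anchor", "covariate", "none"):
        raise WorkflowError(
            f"stage config: batch.mode must be anchor|covariate|none, got "
            f"{cfg['batch']['mode']!r}")
    if not cfg["simulate"]:
        if not cfg["counts"] or not cfg["meta"]:
            raise WorkflowError(
                "stage config: counts and meta paths are required when "
                "simulate is false")
    return cfg


def run_full_analysis(config: str | Path | dict) -> ResultBundle:
    """Execute the full pipeline from a config file or dict."""
    if isinstance(config, (str, Path)):
        raw = yaml.safe_load(Path(config).read_text()) or {}
    else:
        raw = dict(config)
    cfg = _merge_config(raw)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def persist(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        write_table(frame, path)
        manifest[name] = name

    # -- ingest / simulate --------------------------------------------------
    study: SimulatedStudy | None = None
    try:
        if cfg["simulate"]:
            sim_kwargs = dict(cfg["sim"] or {})
            sim_kwargs["seed"] = int(cfg["seed"])
            sim_config = config_from_dict(sim_kwargs)
            study = simulate_study(sim_config)
            counts, meta = study.counts, study.meta
            logger.info("stage=simulate probes=%d assays=%d seed=%d",
                        len(counts.probe_ids), len(counts.assay_ids),
                        sim_config.seed)
        else:
            counts = read_counts(cfg["counts"], format=cfg["counts_format"])
            meta = read_meta(cfg["meta"])
            meta.check_matches(counts)
            logger.info("stage=ingest probes=%d assays=%d",
                        len(counts.probe_ids), len(counts.assay_ids))
    except Exception as exc:
        raise WorkflowError(f"stage ingest: {exc}") from exc

    # -- normalise ----------------------------------------------------------
    mode = cfg["batch"]["mode"]
    include_batch = mode == "covariate"
    anchor = mode == "anchor" and len(meta.batches) > 1
    try:
        norm = cfg["normalization"]
        # with anchor correction the quantile step is deferred until after
        # the additive batch offsets are removed (see apply_quantile)
        expr = normalize_pipeline(
            counts,
            FilterParams(sd_multiplier=float(norm["sd_multiplier"]),
                         pooling=norm["pooling"]),
            pseudocount=float(norm["pseudocount"]),
            quantile=not anchor)
        logger.info("stage=normalize genes_kept=%d", len(expr.gene_ids))
    except Exception as exc:
        raise WorkflowError(f"stage normalize: {exc}") from exc

    # -- batch correction ---------------------------------------------------
    try:
        if anchor:
            offsets = batch_mod.estimate_batch_offsets(expr, meta)
            expr = batch_mod.correct_batches(expr, offsets, meta)
            expr = apply_quantile(expr)
            logger.info("stage=batch mode=anchor batches=%s", meta.batches)
        else:
            logger.info("stage=batch mode=%s (no anchor correction)", mode)
    except Exception as exc:
        raise WorkflowError(f"stage batch: {exc}") from exc

    # -- differential expression --------------------------------------------
    try:
        de_cfg = cfg["de"]
        model = diffexp.ExpressionLinearModel(
            expr, meta, include_batch=include_batch and len(meta.batches) > 1)
        results = model.fit()
        m_tests = int(de_cfg["enfp_m"] or len(expr.gene_ids))
        alpha = (float(de_cfg["alpha"]) if de_cfg["alpha"] is not None
                 else diffexp.enfp_alpha(m_tests, float(de_cfg["enfp_k"])))
        fold = float(de_cfg["fold_threshold"])
        groups = sorted(set(meta.frame["group"]) - {"control"})
        contrasts = de_cfg["contrasts"] or [f"{g}-control" for g in groups]
        de_tables = {c: results.contrast(c, fold_threshold=fold, alpha=alpha)
                     for c in contrasts}
        logger.info("stage=de contrasts=%s alpha=%.4g fold=%g d0=%.3g",
                    contrasts, alpha, fold, results.d0)
    except Exception as exc:
        raise WorkflowError(f"stage de: {exc}") from exc

    # -- Venn partition of group-vs-control signatures ----------------------
    try:
        group_sets = {
            c.split("-", 1)[0]: diffexp.call_significant(t, fold, alpha)
            for c, t in de_tables.items() if c.endswith("-control")}
        partition = (diffexp.venn_partition(group_sets)
                     if len(group_sets) >= 2 else {})
        logger.info("stage=venn regions=%d", len(partition))
    except Exception as exc:
        raise WorkflowError(f"stage venn: {exc}") from exc

    # -- PCA ----------------------------------------------------------------
    try:
        pca_cfg = cfg["pca"]
        pca_res = pca_mod.run_pca(expr)
        top = pca_mod.top_loading_genes(pca_res, component=1,
                                        k=int(pca_cfg["top"]))
        logger.info("stage=pca components=%d pc1_var=%.3f",
                    pca_res.n_components, pca_res.variance_fraction[0])
    except Exception as exc:
        raise WorkflowError(f"stage pca: {exc}") from exc

    # -- enrichment ---------------------------------------------------------
    enr_table: pd.DataFrame | None = None
    try:
        enr_cfg = cfg["enrichment"]
        if enr_cfg["gmt"]:
            sets: GeneSetCollection = read_gene_sets(enr_cfg["gmt"])
            background = set(expr.gene_ids)
            gate_fold = float(enr_cfg["fold_threshold"])
            gate_alpha = float(enr_cfg["alpha"])
            de_union: set[str] = set()
            for t in de_tables.values():
                de_union |= diffexp.call_significant(t, gate_fold, gate_alpha)
            enr_table = enrich_mod.fisher_enrichment(
                de_union & background, sets, background)
            logger.info("stage=enrichment sets=%d de_genes=%d",
                        len(sets), len(de_union & background))
        else:
            logger.info("stage=enrichment skipped (no gene sets supplied)")
    except Exception as exc:
        raise WorkflowError(f"stage enrichment: {exc}") from exc

    # -- persist ------------------------------------------------------------
    try:
        expr_out = expr.values.copy()
        expr_out.insert(0, "gene", expr_out.index)
        persist("expression.tsv", expr_out)
        (outdir / "expression.provenance.json").write_text(
            json.dumps(expr.provenance, indent=1, sort_keys=True) + "\n")
        manifest["expression.provenance.json"] = "expression.provenance.json"
        for c, t in de_tables.items():
            persist(f"de_{c}.tsv", t)
        venn_frame = pd.DataFrame(
            [{"region": r, "n_genes": len(g), "genes": ",".join(sorted(g))}
             for r, g in sorted(partition.items())])
        persist("venn.tsv", venn_frame if not venn_frame.empty
                else pd.DataFrame(columns=["region", "n_genes", "genes"]))
        scores_out = pca_res.scores.copy()
        scores_out.insert(0, "assay_id", scores_out.index)
        persist("pca_scores.tsv", scores_out)
        loadings_out = pca_res.loadings.copy()
        loadings_out.insert(0, "gene", loadings_out.index)
        persist("pca_loadings.tsv", loadings_out)
        persist("pca_top_genes.tsv", top)
        _plot_scores(pca_res, meta, outdir / "pca_scatter.png")
        manifest["pca_scatter.png"] = "pca_scatter.png"
        if enr_table is not None:
            persist("enrichment.tsv", enr_table)
        (outdir / "summary.txt").write_text(
            results.summary(contrasts, fold_threshold=fold, alpha=alpha) + "\n")
        manifest["summary.txt"] = "summary.txt"
        (outdir / "config_snapshot.yaml").write_text(
            yaml.safe_dump(cfg, sort_keys=True))
        manifest["config_snapshot.yaml"] = "config_snapshot.yaml"
        (outdir / "manifest.json").write_text(
            json.dumps(dict(sorted(manifest.items())), indent=1,
                       sort_keys=True) + "\n")
    except Exception as exc:
        raise WorkflowError(f"stage persist: {exc}") from exc

    return ResultBundle(
        expr=expr, de_tables=de_tables, partition=partition, pca=pca_res,
        top_genes=top, enrichment=enr_table, provenance=expr.provenance,
        config=cfg, outdir=outdir, manifest=manifest, study=study)


def _plot_scores(pca_res: pca_mod.PCAResult, meta: SampleTable,
                 path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    group = meta.frame.set_index("assay_id")["group"]
    batch = meta.frame.set_index("assay_id")["batch"].astype(str)
    fig, ax = plt.subplots(figsize=(5, 4))
    markers = {b: m for b, m in zip(sorted(batch.unique()), "o^svD")}
    colors = {"control": "tab:grey", "CR": "tab:blue", "PR": "tab:green",
              "NR": "tab:red"}
    for a in pca_res.scores.index:
        g, b = group[a], batch[a]
        ax.scatter(pca_res.scores.loc[a, "PC1"],
                   pca_res.scores.loc[a, "PC2"]
                   if "PC2" in pca_res.scores else 0.0,
                   c=colors.get(g, "k"), marker=markers.get(b, "o"),
                   label=None)
    vf = pca_res.variance_fraction
    ax.set_xlabel(f"PC1 ({vf[0] * 100:.0f}% of variance)")
    if len(vf) > 1:
        ax.set_ylabel(f"PC2 ({vf[1] * 100:.0f}% of variance)")
    handles = [plt.Line2D([], [], linestyle="", marker="o",
                          color=colors[g], label=g)
               for g in colors if g in set(group)]
    ax.legend(handles=handles, fontsize=8, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
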