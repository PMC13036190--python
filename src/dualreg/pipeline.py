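"""End-to-end pipeline: simulate -> classify -> enrich -> cohort -> report.

A run is described by one YAML config (all seeds explicit) and writes a
run directory of TSV/JSON outputs plus ``manifest.json`` listing every
output file with a SHA-256 checksum, the seeds, thresholds and per-stage
row counts.  Re-running the same config reproduces byte-identical
outputs.  Any stage failure aborts with the stage name and cause.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import DEGClassifier, Thresholds, coregulation_stats
from .cohort import (correlation_analysis, exclusive_genotype_subgroups,
                     pca_reduce, rowscale_for_heatmap, select_subgroups,
                     stage_stratified_dea, subgroup_log2fc_profiles)
from .enrichment import (cluster_terms, cluster_unique_genes, filter_terms,
                         merge_direction_runs, ora_test, term_similarity,
                         write_enrichment_table)
from .io import (read_de_table, read_edge_list, read_expression_cohort,
                 read_gmt, write_de_table, write_expression_cohort, write_gmt)
from .network import annotate_network_nodes
from .simulate import (CohortSimulationConfig, ContrastSimulationConfig,
                       GroupShift, PValueModel, simulate_cohort,
                       simulate_contrasts, simulate_gene_sets, write_truth)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; message carries the stage name and cause."""


def demo_config_path() -> Path:
    """Path of the bundled pure-simulation demo config."""
    return Path(__file__).parent / "data" / "demo_config.yaml"


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return decorator


def _write_tsv(frame: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    if index_label is not None:
        frame = frame.rename_axis(index_label).reset_index()
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def sha256_file(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise PipelineError("stage 'config' failed: config must be a mapping")
    if "seed" not in config:
        raise PipelineError("stage 'config' failed: a top-level seed is required")
    return config


def _contrast_config(block: dict, seed: int) -> ContrastSimulationConfig:
    block = dict(block or {})
    pv = block.pop("p_value_model", None)
    if pv is not None:
        block["p_value_model"] = PValueModel(**pv)
    if "class_proportions" in block:
        block["class_proportions"] = tuple(block["class_proportions"])
    block.setdefault("seed", seed)
    return ContrastSimulationConfig(**block)


def _cohort_config(block: dict, seed: int) -> CohortSimulationConfig:
    block = dict(block or {})
    if "group_sizes" in block:
        block["group_sizes"] = {
            (g["genotype"], g["stage"]): int(g["n"]) for g in block["group_sizes"]}
    if "group_shifts" in block:
        block["group_shifts"] = tuple(GroupShift(**s) for s in block["group_shifts"])
    block.setdefault("seed", seed)
    return CohortSimulationConfig(**block)


@_stage("simulate")
def _run_simulate(config: dict, out: Path, seed: int, state: dict) -> None:
    sim = config.get("simulate")
    if not sim:
        return
    if "contrasts" in sim:
        ccfg = _contrast_config(sim["contrasts"], seed)
        t_l, t_s, t_ls, truth = simulate_contrasts(ccfg)
        state["tables"] = {"L": t_l, "S": t_s, "LS": t_ls}
        state["contrast_truth"] = truth
        for key, table in state["tables"].items():
            write_de_table(table, out / f"contrast_{key}.tsv")
        write_truth(truth, out / "contrast_truth.tsv")
        state["counts"]["simulated_genes"] = ccfg.n_genes
    if "cohort" in sim:
        kcfg = _cohort_config(sim["cohort"], seed)
        cohort, ctruth = simulate_cohort(kcfg)
        state["cohort"] = cohort
        write_expression_cohort(cohort, out / "cohort_tpm.tsv", out / "cohort_meta.tsv")
        write_truth(ctruth, out / "cohort_truth.tsv")
        state["counts"]["simulated_samples"] = cohort.n_samples()
    if "gene_sets" in sim:
        gs_cfg = dict(sim["gene_sets"])
        gs_cfg.setdefault("seed", seed)
        if "set_size" in gs_cfg:
            gs_cfg["set_size"] = tuple(gs_cfg["set_size"])
        universe = state["tables"]["L"].genes if "tables" in state else None
        if universe is None:
            raise ValueError("gene_sets simulation requires simulated contrasts")
        state["gene_sets"] = simulate_gene_sets(
            universe, truth=state.get("contrast_truth"), **gs_cfg)
        write_gmt(state["gene_sets"], out / "gene_sets.gmt")
        state["counts"]["simulated_gene_sets"] = len(state["gene_sets"])


@_stage("classify")
def _run_classify(config: dict, out: Path, thresholds: Thresholds, state: dict) -> None:
    block = config.get("classify", {}) or {}
    if "tables" not in state:
        inputs = block.get("inputs")
        if not inputs:
            raise ValueError("no DE tables: provide classify.inputs or a "
                             "simulate.contrasts block")
        state["tables"] = {
            key.upper(): read_de_table(inputs[key.lower()], key.upper(),
                                       block.get("column_map"))
            for key in ("L", "S", "LS")
        }
    clf = DEGClassifier(lfc_min=thresholds.lfc_min, fdr_max=thresholds.fdr_max)
    clf.fit(state["tables"])
    state["classifier"] = clf

    table = clf.detected_.copy()
    table["label"] = clf.labels_
    _write_tsv(table, out / "classification.tsv", index_label="gene")
    (out / "class_counts.json").write_text(
        json.dumps({"counts": clf.counts_,
                    "patterns": clf.pattern_counts_.to_dict(),
                    "universe": int(len(clf.universe_)),
                    "dropped": int(clf.n_dropped_)}, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    state["counts"]["universe"] = int(len(clf.universe_))
    state["counts"].update({f"n_{k}": v for k, v in clf.counts_.items()})

    summary = coregulation_stats(clf, state["tables"]["L"], state["tables"]["S"],
                                 thresholds)
    state["coregulation"] = summary
    _write_tsv(summary.scatter, out / "coregulation_scatter.tsv", index_label="gene")
    (out / "coregulation.json").write_text(
        json.dumps({"pearson_r": summary.pearson_r, "n_ls": summary.n_ls,
                    "n_inverse": summary.n_inverse,
                    "frac_inverse": summary.frac_inverse},
                   indent=2, sort_keys=True) + "\n", encoding="utf-8")


@_stage("enrich")
def _run_enrich(config: dict, out: Path, seed: int, state: dict) -> None:
    block = config.get("enrich")
    if block is None:
        return
    if "gmt" in block:
        gene_sets = read_gmt(block["gmt"])
    elif "gene_sets" in state:
        gene_sets = state["gene_sets"]
    else:
        raise ValueError("missing enrich input: no 'gmt' path and no simulated "
                         "gene sets")
    clf = state["classifier"]
    annotated = set().union(*gene_sets.sets.values())
    universe = set(clf.universe_) & annotated
    min_hits = int(block.get("min_hits", 4))
    fdr_max = float(block.get("fdr_max", 0.05))
    metric = block.get("metric", "jaccard")
    direction_table = {"L_DEG": "L", "S_DEG": "S", "LS_DEG": "LS"}

    for deg_class in block.get("classes", ["L_DEG", "S_DEG", "LS_DEG"]):
        query = clf.genes_of(deg_class) & universe
        if not query:
            logger.warning("class %s: empty query after universe restriction",
                           deg_class)
            continue
        lfc = state["tables"][direction_table[deg_class]].data["log2fc"]
        up = {g for g in query if lfc.loc[g] > 0}
        down = query - up
        runs = {
            "all": ora_test(query, universe, gene_sets, "all"),
            "up": ora_test(up, universe, gene_sets, "up") if up else None,
            "down": ora_test(down, universe, gene_sets, "down") if down else None,
        }
        empty = runs["all"].iloc[0:0]
        merged = merge_direction_runs(
            runs["up"] if runs["up"] is not None else empty,
            runs["down"] if runs["down"] is not None else empty,
            runs["all"])
        kept = filter_terms(merged, min_hits=min_hits, fdr_max=fdr_max)
        write_enrichment_table(kept, out / f"enrichment_{deg_class}.tsv")
        state["counts"][f"enriched_terms_{deg_class}"] = int(len(kept))
        if len(kept) < 3:
            continue
        sim = term_similarity(kept, metric=metric)
        result = cluster_terms(sim, k_max=min(block.get("k_max", 8), len(kept) - 1),
                               seed=seed)
        _write_tsv(sim, out / f"term_similarity_{deg_class}.tsv", index_label="term_id")
        labels = result.labels.to_frame()
        labels["display_order"] = [result.order.index(t) for t in labels.index]
        _write_tsv(labels, out / f"term_clusters_{deg_class}.tsv",
                   index_label="term_id")
        curve = pd.DataFrame(sorted(result.silhouette_curve.items()),
                             columns=["k", "mean_silhouette"])
        _write_tsv(curve, out / f"silhouette_{deg_class}.tsv")
        unique = cluster_unique_genes(kept, result.labels)
        _write_tsv(pd.DataFrame(
            [{"cluster": c, "genes": ",".join(sorted(g))}
             for c, g in sorted(unique.items())]),
            out / f"cluster_unique_genes_{deg_class}.tsv")


@_stage("cohort")
def _run_cohort(config: dict, out: Path, thresholds: Thresholds, state: dict) -> None:
    block = config.get("cohort")
    if block is None:
        return
    if "cohort" not in state:
        if "matrix" not in block or "metadata" not in block:
            raise ValueError("missing cohort input: provide cohort.matrix and "
                             "cohort.metadata or a simulate.cohort block")
        state["cohort"] = read_expression_cohort(block["matrix"], block["metadata"])
    cohort = state["cohort"]

    defs = exclusive_genotype_subgroups(tuple(block.get(
        "genotypes", ("WT", "LKB1", "SMARCA4", "TP53"))))
    subgroups = select_subgroups(cohort, defs, allow_overlap=True)
    _write_tsv(pd.DataFrame(
        [{"subgroup": name, "n": len(samples),
          "samples": ",".join(samples)} for name, samples in subgroups.items()]),
        out / "subgroups.tsv")
    state["counts"].update({f"subgroup_{k}": len(v) for k, v in subgroups.items()})

    profiles = subgroup_log2fc_profiles(cohort, subgroups)
    if len(profiles) >= 2:
        corr = correlation_analysis(profiles)
        _write_tsv(corr, out / "subgroup_correlation.tsv", index_label="subgroup")
        _write_tsv(rowscale_for_heatmap(corr, mode="minmax"),
                   out / "subgroup_correlation_rowscaled.tsv", index_label="subgroup")

    if block.get("pca", True) and cohort.n_samples() >= 3:
        scores, evr = pca_reduce(cohort.expression,
                                 variance_target=block.get("variance_target", 0.8),
                                 max_components=block.get("max_components", 10))
        _write_tsv(scores, out / "pca_scores.tsv", index_label="sample_id")
        _write_tsv(pd.DataFrame({"component": scores.columns,
                                 "explained_variance_ratio": evr}),
                   out / "pca_variance.tsv")

    if block.get("stage_dea", True):
        detector = stage_stratified_dea(cohort, thresholds,
                                        min_group_size=block.get("min_group_size", 2))
        _write_tsv(detector.markers_, out / "stage_markers.tsv")
        state["counts"]["stage_markers"] = int(len(detector.markers_))


@_stage("annotate_network")
def _run_annotate(config: dict, out: Path, state: dict) -> None:
    block = config.get("annotate_network")
    if block is None:
        return
    if "edges" not in block:
        raise ValueError("missing annotate_network.edges path")
    edges = read_edge_list(block["edges"])
    nodes, kept = annotate_network_nodes(
        edges, state["classifier"], state["tables"],
        min_score=int(block.get("min_score", 600)))
    _write_tsv(nodes, out / "network_nodes.tsv", index_label="gene")
    _write_tsv(kept.edges, out / "network_edges.tsv")
    state["counts"]["network_nodes"] = int(len(nodes))
    state["counts"]["network_edges"] = int(len(kept))


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Execute the pipeline described by a config mapping or YAML path.

    Stages: simulate (optional) -> classify -> enrich (per DEG class,
    optional) -> cohort (optional) -> annotate_network (optional) ->
    manifest.  Returns the run directory.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    if "seed" not in config:
        raise PipelineError("stage 'config' failed: a top-level seed is required")
    seed = int(config["seed"])
    thresholds = Thresholds(**(config.get("thresholds") or {}))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    state: dict = {"counts": {}}
    _run_simulate(config, out, seed, state)
    _run_classify(config, out, thresholds, state)
    _run_enrich(config, out, seed, state)
    _run_cohort(config, out, thresholds, state)
    _run_annotate(config, out, state)

    files = sorted(p for p in out.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package": "dualreg",
        "version": __version__,
        "seed": seed,
        "thresholds": asdict(thresholds),
        "counts": state["counts"],
        "files": {p.name: sha256_file(p) for p in files},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return out
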