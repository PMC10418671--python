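"""End-to-end orchestration of the discrimination analysis.

``run_all`` executes (optionally) simulation, preprocessing, block building
(functional metabolite blocks + Ward lipid clusters), per-block composite
scores, the weighted hierarchical PLS-DA with permutation validation and
CV-ANOVA, block and feature selection, the partial-correlation network with
betweenness, and pathway over-representation; every intermediate is written
as CSV/JSON under the output directory and listed in a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import AnalysisConfig, FeatureTable, OmniblockError, write_feature_table
from .enrich import PathwayCatalog, enrich, results_frame, write_pathway_catalog
from .latent import choose_components, cv_anova, fit_plsda, compute_vip, permutation_test
from .multiblock import (
    BlockMap,
    block_scores,
    cluster_lipids,
    fit_hierarchical,
    functional_block_map,
    select_blocks,
    weight_blocks,
    write_block_map,
)
from .network import betweenness, build_network, export_graph, partial_correlations
from .preprocess import run_preprocess, scale_for_model
from .select import Signature, feature_statistics, select_features
from .simulate import SyntheticSpec, generate_pathway_catalog, generate_table, write_ground_truth

__all__ = ["run_all", "render_report"]

_FLOAT_FMT = "%.12g"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path, **kw) -> Path:
    frame.to_csv(path, float_format=_FLOAT_FMT, na_rep="NA", **kw)
    return path


def run_all(
    config: AnalysisConfig | None = None,
    out_dir: str | Path = "omniblock_run",
    table: FeatureTable | None = None,
    simulate_spec: SyntheticSpec | None = None,
    catalog: PathwayCatalog | None = None,
    n_pathways: int = 20,
) -> dict:
    """Run the full pipeline; returns the manifest (also written as JSON).

    Either ``table`` (a real feature table) or ``simulate_spec`` must be
    given.  Fully deterministic for a fixed config seed and inputs; the
    manifest records a sha256 hash of every stage output.
    """
    config = (config or AnalysisConfig()).validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "inputs"
    try:
        truth = None
        if table is None:
            if simulate_spec is None:
                simulate_spec = SyntheticSpec(seed=config.seed)
            table, truth = generate_table(simulate_spec)
            ipath, spath, fpath = write_feature_table(table, out / "simulated")
            for name, p in (("intensities", ipath), ("sample_meta", spath), ("feature_meta", fpath)):
                record(f"simulated_{name}", p)
            record("ground_truth", write_ground_truth(truth, out / "simulated" / "ground_truth.csv"))
            if catalog is None:
                catalog = generate_pathway_catalog(simulate_spec, n_pathways, truth)
                record("pathway_catalog", write_pathway_catalog(catalog, out / "simulated" / "pathways.tsv"))
        (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
        record("resolved_config", out / "config.json")

        stage = "preprocess"
        processed, report = run_preprocess(table, config)
        record("preprocess_summary", _write_csv(report.summary(), out / "preprocess_summary.csv", index=False))
        record("qc_cv", _write_csv(report.qc_cv.rename("qc_cv").to_frame(), out / "qc_cv.csv"))
        if report.outliers is not None:
            record("outliers", _write_csv(report.outliers, out / "outliers.csv"))
        ppath = out / "processed"
        ipath, spath, fpath = write_feature_table(processed, ppath)
        record("processed_intensities", ipath)

        stage = "blocks"
        Z, y, scaler = scale_for_model(processed, mode=config.scaling)
        feature_ids = scaler.feature_ids
        func_map, unassigned = functional_block_map(processed, "metabolomics")
        func_map = BlockMap(
            {b: [f for f in feats if f in set(feature_ids)] for b, feats in func_map.blocks.items()
             if any(f in set(feature_ids) for f in feats)},
            kind="functional",
        )
        lip_ids = [
            f for f in feature_ids
            if processed.feature_meta.loc[f, "assay"] == "lipidomics"
        ]
        col_index = {f: j for j, f in enumerate(feature_ids)}
        lipid_map = None
        if lip_ids:
            k = min(config.n_lipid_clusters, len(lip_ids))
            lipid_map = cluster_lipids(Z[:, [col_index[f] for f in lip_ids]], lip_ids, k)
            block_map = func_map.merged(lipid_map)
        else:
            block_map = func_map
        record("block_map", write_block_map(block_map, out / "block_map.tsv"))

        stage = "block_scores"
        study_ids = processed.sample_ids[processed.study_mask]
        raw_scores = block_scores(Z, y, feature_ids, block_map,
                                  n_orthogonal=config.n_orthogonal, sample_ids=study_ids)
        weighted = weight_blocks(raw_scores, config.weight_scheme)
        record("block_scores", _write_csv(weighted.scores, out / "block_scores.csv"))

        stage = "hierarchical_model"
        M = weighted.matrix()
        Mc = M - M.mean(axis=0)
        A = choose_components(Mc, y, max_A=config.max_components,
                              n_folds=config.n_folds, seed=config.seed)
        model, block_vips = fit_hierarchical(weighted, y, A=A)
        val = permutation_test(Mc, y, A, n_permutations=config.n_permutations,
                               seed=config.seed, n_folds=config.n_folds)
        f_stat, df1, df2, f_p = cv_anova(val)
        scores_frame = pd.DataFrame(
            model.scores, index=study_ids,
            columns=[f"t{a + 1}" for a in range(model.A)],
        )
        scores_frame.insert(0, "group", y)
        record("hier_scores", _write_csv(scores_frame, out / "hierarchical_scores.csv"))
        model_stats = {
            "n_components": A,
            "r2x": model.r2x,
            "r2y": model.r2y,
            "q2": val.q2,
            "permutation_p": val.perm_p,
            "cv_anova_F": f_stat,
            "cv_anova_df1": df1,
            "cv_anova_df2": df2,
            "cv_anova_p": f_p,
        }
        (out / "hierarchical_model.json").write_text(json.dumps(model_stats, indent=2, sort_keys=True))
        record("hier_model", out / "hierarchical_model.json")

        stage = "block_selection"
        block_sel = select_blocks(block_vips, weighted, y,
                                  vip_threshold=config.vip_threshold, alpha=config.alpha)
        record("block_selection", _write_csv(block_sel, out / "block_selection.csv"))

        stage = "feature_selection"
        study_inten = processed.intensities.loc[processed.study_mask, feature_ids]
        classes = sorted(set(y.tolist()))
        case_label = classes[1] if "case" not in classes else "case"
        fstats = feature_statistics(study_inten, y, case_label, method="welch_t")
        A_feat = choose_components(Z, y, max_A=config.max_components,
                                   n_folds=config.n_folds, seed=config.seed)
        flat = fit_plsda(Z, y, A=A_feat)
        feat_vips = pd.Series(compute_vip(flat), index=feature_ids, name="vip")
        signature, records = select_features(
            feat_vips, fstats, vip_threshold=config.vip_threshold,
            alpha=config.alpha, use_adjusted=config.use_adjusted, name="all",
        )
        records = records.join(processed.feature_meta[["assay", "annotation"]])
        record("feature_selection", _write_csv(records, out / "feature_selection.csv"))

        stage = "network"
        pcor, lam, pvals = partial_correlations(raw_scores.scores)
        node_attrs = block_sel[["q", "p"]].reindex(pcor.index)
        net = build_network(pcor, pvals, p_threshold=config.network_p_threshold,
                            shrinkage=lam, node_attrs=node_attrs)
        bc = betweenness(net)
        graphml, sif = export_graph(net, out / "network")
        record("network_graphml", graphml)
        record("network_sif", sif)
        nodes_frame = node_attrs.join(bc)
        record("network_nodes", _write_csv(nodes_frame, out / "network_nodes.csv"))
        edges = [
            {"source": u, "target": v, "pcor": d["pcor"], "p": d["p"]}
            for u, v, d in sorted(net.graph.edges(data=True))
        ]
        record("network_edges", _write_csv(pd.DataFrame(edges), out / "network_edges.csv", index=False))
        manifest["network_shrinkage"] = lam

        stage = "enrichment"
        if catalog is not None:
            met_ids = [f for f in signature.features
                       if processed.feature_meta.loc[f, "assay"] == "metabolomics"]
            selected_names = [str(processed.feature_meta.loc[f, "annotation"] or f)
                              for f in met_ids]
            universe_names = [
                str(processed.feature_meta.loc[f, "annotation"] or f)
                for f in feature_ids
                if processed.feature_meta.loc[f, "assay"] == "metabolomics"
            ]
            restricted = catalog.restricted(universe_names)
            if restricted.pathways:
                results = enrich(selected_names, restricted)
                record("enrichment", _write_csv(results_frame(results), out / "enrichment.csv", index=False))

        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest["n_features_processed"] = int(processed.n_features)
        manifest["n_selected_features"] = int(records["selected"].sum())
        manifest["n_selected_blocks"] = int(block_sel["selected"].sum())
        manifest["model"] = model_stats
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except OmniblockError as err:
        raise OmniblockError(f"pipeline stage {stage!r} failed: {err}") from err


def render_report(manifest: dict, out_path: str | Path | None = None) -> str:
    """Human-readable summary of a completed run (markdown text).

    Sections whose stage output is missing are skipped with a notice; all
    numbers are read back from the stage CSVs so the report cannot diverge
    from them.
    """
    outputs = manifest.get("outputs", {})
    lines = ["# omniblock run report", ""]
    model = manifest.get("model")
    if model:
        lines += [
            "## Hierarchical PLS-DA",
            f"- components: {model['n_components']}",
            f"- R2Y = {model['r2y']:.3f}, Q2 = {model['q2']:.3f}",
            f"- permutation p = {model['permutation_p']:.4g} "
            f"({manifest['config']['n_permutations']} permutations)",
            f"- CV-ANOVA F = {model['cv_anova_F']:.3f} "
            f"(df {model['cv_anova_df1']}, {model['cv_anova_df2']}), p = {model['cv_anova_p']:.3g}",
            "",
        ]
    def frame_of(name):
        if name not in outputs:
            return None
        path = Path(outputs[name]["path"])
        return pd.read_csv(path) if path.exists() else None

    blocks = frame_of("block_selection")
    if blocks is not None:
        sel = blocks[blocks["selected"]]
        lines += [
            "## Block ranking",
            f"- {len(sel)} of {len(blocks)} blocks selected "
            f"(VIP > threshold and B-Y q < alpha)",
            "",
            blocks.head(10).to_string(index=False),
            "",
        ]
    else:
        lines += ["## Block ranking", "- stage output missing, section skipped", ""]
    feats = frame_of("feature_selection")
    if feats is not None:
        sel = feats[feats["selected"]]
        lines += [
            "## Feature selection",
            f"- {len(sel)} of {len(feats)} features selected",
        ]
        if len(sel):
            lines += ["", "Top 4 by VIP:", "",
                      sel.head(4)[["feature_id", "annotation", "vip", "fold_change", "p"]]
                      .to_string(index=False)]
        else:
            lines += ["- zero selected features"]
        lines += [""]
    nodes = frame_of("network_nodes")
    if nodes is not None:
        top = nodes.sort_values("betweenness", ascending=False).head(5)
        lines += ["## Network", "Top betweenness nodes:", "", top.to_string(index=False), ""]
    enr = frame_of("enrichment")
    if enr is not None and len(enr):
        lines += ["## Enrichment", "", enr.head(5).to_string(index=False), ""]
    text = "\n".join(lines)
    if out_path is not None:
        out_path = Path(out_path)
        out_path.write_text(text)
        _maybe_score_plot(outputs, out_path.with_name("score_plot.png"))
    return text


def _maybe_score_plot(outputs: dict, path: Path) -> None:
    """Score scatter of the first two hierarchical components (optional;
    skipped silently when matplotlib or a second component is absent)."""
    entry = outputs.get("hier_scores")
    if entry is None:
        return
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    frame = pd.read_csv(entry["path"], index_col=0)
    if "t2" not in frame.columns:
        return
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, sub in frame.groupby("group"):
        ax.scatter(sub["t1"], sub["t2"], s=12, label=str(group), alpha=0.7)
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel("t[1]")
    ax.set_ylabel("t[2]")
    ax.legend(title="group", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
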