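"""Cross-layer integration matrix and end-to-end pipeline orchestration.

The integration heatmap places one feature per row (a genus' abundance, the
connectivity significant-pair count, a GO term's collapsed tpm, a histology
parameter) against diet × timepoint groups as columns, and min-max scales
each row to [0, 1] so that, per feature, the group where it is most present
reads 1 and the group where it is least present reads 0.  A constant row
scales to all zeros.  The scaling is purely descriptive — no latent-factor
fusion is attempted.

:func:`run_pipeline` drives the whole synthetic study: simulate every
requested layer, run its analysis at the default thresholds, write TSV
outputs and a manifest, and assemble the integration matrix.  Identical
config + seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .community import filter_low_count_asvs, log_transform, min_depth, ordinate, rarefy
from .connectivity import (
    NetworkConfig,
    build_network,
    classify_edges,
    eligible_taxa,
    pairwise_association,
    significant_pair_summary,
)
from .containers import AbundanceTable, CountTable
from .gonetwork import GONetworkConfig, build_go_edges, export_network, select_nodes
from .histology import LabelMask, scale_histology, section_metrics
from .simulate import (
    CommunitySimConfig,
    ExpressionSimConfig,
    SectionSimConfig,
    simulate_asv_table,
    simulate_expression,
    simulate_gut_section,
)
from .transcriptome import (
    collapse_to_go,
    gene_scores,
    go_fold_change,
    gsr_enrichment,
    within_group_dissimilarity,
)

logger = logging.getLogger(__name__)


def group_key(diet, timepoint) -> str:
    return f"{diet}@{timepoint}"


# ---------------------------------------------------------------- summaries

def summarize_genus(ab: AbundanceTable, by=("diet", "timepoint"), top_k=None) -> pd.DataFrame:
    """Group-mean relative abundance per taxon (feature × group)."""
    labels = ab.group_labels(by)
    out = {}
    for g in pd.unique(labels):
        out[g] = ab.abundances.loc[:, labels.index[labels == g]].mean(axis=1)
    table = pd.DataFrame(out)
    if top_k is not None:
        order = table.mean(axis=1).sort_values(ascending=False).index[:top_k]
        table = table.loc[order]
    return table


def summarize_connectivity(sig_counts: dict) -> pd.DataFrame:
    """Significant-pair counts as a single feature row."""
    return pd.DataFrame({g: [c] for g, c in sig_counts.items()},
                        index=["significant_pairs"])


def summarize_go(go_matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Group-mean collapsed tpm per GO term (feature × group)."""
    out = {}
    for g in pd.unique(groups):
        out[g] = go_matrix.loc[:, groups.index[groups == g]].mean(axis=1)
    return pd.DataFrame(out)


def summarize_histology(scaled: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Group means of the 0–1 scaled histology metrics (feature × group)."""
    out = {}
    for g in pd.unique(groups):
        out[g] = scaled.loc[groups.index[groups == g]].mean(axis=0)
    return pd.DataFrame(out)


_SUMMARIZERS = {
    "genus": summarize_genus,
    "connectivity": summarize_connectivity,
    "go": summarize_go,
    "histology": summarize_histology,
}


def summarize_layer(tag: str, *args, **kwargs) -> pd.DataFrame:
    """Dispatch to the per-layer group summary by layer tag."""
    if tag not in _SUMMARIZERS:
        raise ValueError(f"unknown layer tag {tag!r}; known: {sorted(_SUMMARIZERS)}")
    return _SUMMARIZERS[tag](*args, **kwargs)


@dataclass
class IntegrationMatrix:
    """Feature × group matrix, each row min-max scaled to [0, 1].

    Rows carry a (layer, feature) MultiIndex so every feature stays traceable
    to its source layer.
    """

    values: pd.DataFrame

    @property
    def layers(self) -> list:
        return sorted(set(self.values.index.get_level_values(0)))


def minmax_scale_rows(table: pd.DataFrame) -> IntegrationMatrix:
    """Per-row (x − min)/(max − min); constant rows become all zeros.

    NaN cells (a group absent from a layer) stay NaN and are ignored by the
    scaling.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 group columns")
    vals = table.to_numpy(dtype=float)
    lo = np.nanmin(vals, axis=1, keepdims=True)
    hi = np.nanmax(vals, axis=1, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span > 0, (vals - lo) / span, 0.0)
    scaled[np.isnan(vals)] = np.nan
    out = pd.DataFrame(scaled, index=table.index, columns=table.columns)
    return IntegrationMatrix(out)


def assemble_integration(layer_tables: dict) -> IntegrationMatrix:
    """Stack per-layer feature × group tables and scale each row to [0, 1]."""
    pieces = []
    for layer, table in layer_tables.items():
        t = table.copy()
        t.index = pd.MultiIndex.from_product([[layer], t.index],
                                             names=["layer", "feature"])
        pieces.append(t)
    stacked = pd.concat(pieces, axis=0)
    return minmax_scale_rows(stacked)


# ---------------------------------------------------------------- pipeline

def _jsonable(obj):
    """Stringify dict keys (e.g. (diet, timepoint) tuples) for the manifest."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _derive_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _microbiome_stage(cfg: dict, seed: int, out: Path, manifest: dict) -> dict:
    if "counts" in cfg:
        table = gio.read_count_table(cfg["counts"], cfg["meta"])
    else:
        sim_kwargs = dict(cfg.get("simulate", {}))
        sim = CommunitySimConfig(seed=_derive_seed(seed, "microbiome"), **sim_kwargs)
        table, _truth = simulate_asv_table(sim)
    table = filter_low_count_asvs(table, cfg.get("filter_max", 2))
    depth_cfg = cfg.get("rarefy_depth", "min")
    depth = min_depth(table) if depth_cfg == "min" else int(depth_cfg)
    rare = rarefy(table, depth, seed=_derive_seed(seed, "rarefy"))
    ab = rare.relative_abundance()

    gio.write_table(rare.counts, out / "counts_rarefied.tsv", "taxon")
    gio.write_metadata(rare.metadata, out / "sample_metadata.tsv")
    gio.write_table(ab.abundances, out / "relative_abundance.tsv", "taxon")

    # constrained ordination of the log-transformed abundances by diet,
    # within each timepoint
    ordinations = {}
    for tp in pd.unique(rare.metadata["timepoint"]):
        samples = rare.metadata.index[rare.metadata["timepoint"] == tp]
        if len(samples) < 3:
            continue
        response = log_transform(ab).loc[:, samples].T
        res = ordinate(response, rare.metadata.loc[samples, "diet"],
                       n_perm=cfg.get("n_perm", 500),
                       seed=_derive_seed(seed, f"rda{tp}"))
        ordinations[str(tp)] = res
        res.sample_scores.to_csv(out / f"rda_scores_{tp}.tsv", sep="\t")
    manifest["microbiome"] = {"depth": depth, "n_taxa": len(rare.taxa),
                              "rda_p": {tp: r.p_value for tp, r in ordinations.items()}}

    # connectivity per diet at the network timepoint on gut samples
    net_cfg = NetworkConfig(**cfg.get("network", {}))
    net_tp = cfg.get("network_timepoint")
    sig_counts = {}
    networks = {}
    meta = rare.metadata
    timepoints = pd.unique(meta["timepoint"]) if net_tp is None else [net_tp]
    for tp in timepoints:
        assocs = {}
        universe = set()
        for diet in pd.unique(meta["diet"]):
            samples = meta.index[(meta["diet"] == diet) & (meta["timepoint"] == tp)
                                 & (meta["source"] == "gut")]
            if len(samples) < 4:
                continue
            taxa = eligible_taxa(rare, net_cfg, samples)
            universe |= set(taxa)
            assocs[diet] = (samples, taxa)
        nets_tp = {}
        assoc_tables = {}
        for diet, (samples, taxa) in assocs.items():
            assoc = pairwise_association(ab, net_cfg, samples, taxa=taxa,
                                         group_label=group_key(diet, tp))
            assoc_tables[diet] = assoc
            sizes = ab.abundances.loc[sorted(universe), samples].mean(axis=1)
            nets_tp[diet] = build_network(assoc, net_cfg, sizes, group_key(diet, tp))
            assoc.to_csv(out / f"associations_{diet}_{tp}.tsv", sep="\t", index=False)
        if len(nets_tp) >= 2:
            classify_edges(nets_tp).to_csv(out / f"edge_classes_{tp}.tsv",
                                           sep="\t", index=False)
        summary = significant_pair_summary(assoc_tables, net_cfg)
        for diet, count in summary.sig_counts.items():
            sig_counts[group_key(diet, tp)] = count
        networks[str(tp)] = nets_tp
    manifest["connectivity"] = {"sig_counts": sig_counts,
                                "config": vars(net_cfg)}
    return {"table": rare, "abundance": ab, "sig_counts": sig_counts,
            "networks": networks, "ordinations": ordinations}


def _transcriptome_stage(cfg: dict, seed: int, out: Path, manifest: dict) -> dict:
    if "expr" in cfg:
        expr = gio.read_table(cfg["expr"])
        meta = gio.read_metadata(cfg["meta"])
        ann = gio.read_annotation(cfg["ann"])
    else:
        sim_kwargs = dict(cfg.get("simulate", {}))
        sim = ExpressionSimConfig(seed=_derive_seed(seed, "expression"), **sim_kwargs)
        expr, meta, ann, _truth = simulate_expression(sim)
    control = cfg.get("control", "control")
    treatments = cfg.get("treatments", ["butyrate", "saponin"])
    tp = cfg.get("timepoint", 68)
    n_resample = cfg.get("n_resample", 2000)

    go_matrix = collapse_to_go(expr, ann)
    labels = meta["diet"].astype(str) + "@" + meta["timepoint"].astype(str)
    go_summary = summarize_go(go_matrix, labels)
    gio.write_table(go_matrix, out / "go_collapsed_tpm.tsv", "term")

    ctrl_samples = meta.index[(meta["diet"] == control) & (meta["timepoint"] == tp)]
    results = {}
    for trt in treatments:
        trt_samples = meta.index[(meta["diet"] == trt) & (meta["timepoint"] == tp)]
        scores = gene_scores(expr, ctrl_samples, trt_samples)
        gsr_p = gsr_enrichment(scores, ann, n_resample=n_resample,
                               seed=_derive_seed(seed, f"gsr-{trt}"))
        fc = go_fold_change(go_matrix, ctrl_samples, trt_samples)
        res = pd.DataFrame({"log2FC": fc, "gsr_p": gsr_p}).dropna()
        results[f"{control}-vs-{trt}"] = res
        res.to_csv(out / f"go_results_{trt}.tsv", sep="\t", index_label="term")

    go_net_cfg = GONetworkConfig(**cfg.get("go_network", {}))
    nodes = select_nodes(results, go_net_cfg)
    net = build_go_edges(nodes, ann, results, go_net_cfg)
    export_network(net, out / "go_network.graphml")

    dist, test = within_group_dissimilarity(expr, labels)
    dist.to_csv(out / "bray_curtis_within_group.tsv", sep="\t", index=False)
    manifest["transcriptome"] = {
        "n_genes": int(expr.shape[0]), "n_terms": len(ann),
        "go_nodes": len(nodes), "go_edges": len(net.edges),
        "dissimilarity_test": {"test": test.test, "p": test.p_value},
    }
    return {"expr": expr, "meta": meta, "ann": ann, "go_matrix": go_matrix,
            "go_summary": go_summary, "results": results, "network": net,
            "labels": labels}


def _histology_stage(cfg: dict, seed: int, out: Path, manifest: dict) -> dict:
    groups_cfg = cfg.get("groups")
    if groups_cfg is None:
        raise ValueError("histology stage requires a 'groups' mapping")
    n_sections = cfg.get("n_sections", 5)
    rows = {}
    group_of = {}
    for gkey, params in groups_cfg.items():
        for k in range(n_sections):
            sec = SectionSimConfig(
                seed=_derive_seed(seed, f"section-{gkey}-{k}"), **params
            )
            mask, legend, _truth = simulate_gut_section(sec)
            lm = LabelMask(mask, {k: v for k, v in legend.items() if k != "pixel_size_um"},
                           legend["pixel_size_um"])
            sid = f"{gkey}_s{k}"
            rows[sid] = section_metrics(lm)
            group_of[sid] = gkey
    metrics = pd.DataFrame.from_dict(rows, orient="index")
    scaled = scale_histology(metrics)
    gio.write_table(metrics, out / "histology_metrics.tsv", "section")
    gio.write_table(scaled, out / "histology_metrics_scaled.tsv", "section")
    manifest["histology"] = {"n_sections": int(metrics.shape[0]),
                             "features": list(metrics.columns)}
    return {"metrics": metrics, "scaled": scaled,
            "groups": pd.Series(group_of)}


def run_pipeline(config, out_dir=None) -> dict:
    """Execute the requested stages and assemble the integration matrix.

    ``config`` is a dict (or a path to a YAML file) with optional keys
    ``microbiome``, ``transcriptome``, ``histology`` and a global ``seed``.
    Stage randomness is derived from the global seed per stage name, so any
    subset of stages is reproducible in isolation.
    """
    if not isinstance(config, dict):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "gutweave_run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "stages": list(
        k for k in ("microbiome", "transcriptome", "histology") if k in config)}
    if not manifest["stages"]:
        raise ValueError("config requests no stages")

    layer_tables = {}
    outputs: dict = {}
    if "microbiome" in config:
        res = _microbiome_stage(config["microbiome"], seed, out, manifest)
        outputs["microbiome"] = res
        layer_tables["genus"] = summarize_genus(
            res["abundance"], top_k=config["microbiome"].get("top_k", 15))
        if res["sig_counts"]:
            layer_tables["connectivity"] = summarize_connectivity(res["sig_counts"])
    if "transcriptome" in config:
        res = _transcriptome_stage(config["transcriptome"], seed, out, manifest)
        outputs["transcriptome"] = res
        layer_tables["go"] = res["go_summary"]
    if "histology" in config:
        res = _histology_stage(config["histology"], seed, out, manifest)
        outputs["histology"] = res
        layer_tables["histology"] = summarize_histology(res["scaled"], res["groups"])

    matrix = assemble_integration(layer_tables)
    matrix.values.to_csv(out / "integration_matrix.tsv", sep="\t")
    outputs["integration"] = matrix

    manifest["parameters"] = _jsonable(
        {k: v for k, v in config.items() if k not in ("out_dir",)}
    )
    manifest["checksums"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    outputs["manifest"] = manifest
    return outputs
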