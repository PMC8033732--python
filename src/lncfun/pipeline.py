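"""End-to-end orchestration: simulate/load -> DE -> co-expression ->
function prediction -> cis/trans networks -> qPCR, with a run manifest.

Every stage writes plain-text TSV/SIF/GMT outputs into the run directory,
and the manifest records the configuration hash, seed, package version and
per-stage feature counts. Outputs are a pure function of (inputs, config,
seed): rerunning with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .coexpression import build_coexpression_edges, top_n_edges
from .diffexpr import differential_expression, log2_transform
from .enrich import annotate_lncrnas
from .expression_io import (
    read_expression_matrix,
    read_gene_loci,
    read_gene_sets,
    write_network,
)
from .qpcr import concordance_check, delta_delta_ct
from .regnet import build_networks, find_cis_pairs, find_trans_links, summarize_network
from .synthetic_data import SimConfig, generate_qpcr_cts, write_dataset

__all__ = ["RunConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """All pipeline thresholds (defaults = the published analysis values)
    plus input locations or a simulation request."""

    outdir: str = "lncfun_run"
    seed: int = 0
    simulate: bool = True
    # input paths, used when simulate is False
    matrix_path: str | None = None
    design_path: str | None = None
    loci_path: str | None = None
    functional_gmt: str | None = None
    functional_category: str = "GO_BP"
    tf_gmt: str | None = None
    cts_path: str | None = None
    # group labels (case first)
    case_group: str = "AR"
    control_group: str = "nonAR"
    # thresholds
    fc_threshold: float = 2.0
    de_p_threshold: float = 0.05
    r_threshold: float = 0.8
    pcc_p_threshold: float = 0.05
    enrich_p_threshold: float = 0.05
    fdr_threshold: float = 0.01
    cis_window: int = 100_000
    top_pairs: int = 500
    top_tf_pairs: int = 100
    top_core: int = 10
    # documented alternatives
    equal_var: bool = True
    cis_mode: str = "gap"
    # simulation parameters (seed is overridden by the run seed)
    sim: dict = field(default_factory=dict)
    # qPCR validation panel size when simulating
    n_qpcr_genes: int = 6
    qpcr_ct_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "fc_threshold", "de_p_threshold", "r_threshold", "pcc_p_threshold",
            "enrich_p_threshold", "fdr_threshold", "cis_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.simulate and (self.matrix_path is None or self.design_path is None):
            raise ValueError("matrix_path and design_path are required unless simulating")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _manifest_config(config: RunConfig) -> dict:
    # the run directory is where the manifest lives, not an analysis input;
    # excluding it keeps reruns byte-identical wherever they are written
    data = config.to_dict()
    data.pop("outdir")
    return data


def _config_hash(config: RunConfig) -> str:
    canonical = json.dumps(_manifest_config(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, writing outputs under ``config.outdir``.

    Returns the manifest (also written as ``manifest.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    truth = None

    # --- stage: inputs ------------------------------------------------------
    try:
        if config.simulate:
            sim = SimConfig(**{**config.sim, "seed": config.seed})
            indir = outdir / "inputs"
            matrix, loci, collections, truth = write_dataset(sim, indir)
            functional = collections["GO_BP"]
            tf_collection = collections["TF"]
        else:
            matrix = read_expression_matrix(config.matrix_path, config.design_path)
            loci = read_gene_loci(config.loci_path) if config.loci_path else None
            functional = (
                read_gene_sets(config.functional_gmt, config.functional_category)
                if config.functional_gmt
                else None
            )
            tf_collection = read_gene_sets(config.tf_gmt, "TF") if config.tf_gmt else None
    except Exception as exc:  # noqa: BLE001 - rethrown with stage name
        raise StageError("inputs", exc) from exc

    # --- stage: differential expression -------------------------------------
    try:
        log2_matrix = log2_transform(matrix) if matrix.scale == "linear" else matrix
        de = differential_expression(
            log2_matrix,
            config.case_group,
            config.control_group,
            fc_threshold=config.fc_threshold,
            p_threshold=config.de_p_threshold,
            equal_var=config.equal_var,
        )
        de.index.name = "feature_id"
        de.to_csv(outdir / "de.tsv", sep="\t", float_format="%.10g")
        sig = de[de["significant"]]
        de_lncrnas = sorted(sig.index[sig["feature_class"] == "lncRNA"])
        de_mrnas = sorted(sig.index[sig["feature_class"] == "mRNA"])
        counts["de_lncrnas"] = len(de_lncrnas)
        counts["de_mrnas"] = len(de_mrnas)
    except Exception as exc:
        raise StageError("differential_expression", exc) from exc

    # --- stage: co-expression ------------------------------------------------
    try:
        edges = build_coexpression_edges(
            log2_matrix,
            de_lncrnas,
            de_mrnas,
            r_threshold=config.r_threshold,
            p_threshold=config.pcc_p_threshold,
        )
        edges.to_csv(outdir / "edges.tsv", sep="\t", index=False, float_format="%.10g")
        top = top_n_edges(edges, config.top_pairs)
        top.to_csv(outdir / "edges_top.tsv", sep="\t", index=False, float_format="%.10g")
        import networkx as nx

        net = nx.DiGraph()
        for e in top.itertuples(index=False):
            net.add_node(e.lncrna_id, node_type="lncRNA")
            net.add_node(e.mrna_id, node_type="mRNA")
            net.add_edge(e.lncrna_id, e.mrna_id, interaction=f"coexp{e.sign}")
        write_network(net, outdir / "coexpression.sif", "sif", allow_empty=True)
        counts["coexpression_edges"] = len(edges)
    except Exception as exc:
        raise StageError("coexpression", exc) from exc

    universe = sorted(matrix.features_of_class("mRNA"))

    # --- stage: function prediction ------------------------------------------
    try:
        if functional is not None and len(edges):
            annotation = annotate_lncrnas(
                edges,
                functional,
                universe,
                p_threshold=config.enrich_p_threshold,
                fdr_threshold=config.fdr_threshold,
            )
            annotation.annotations.to_csv(
                outdir / "annotations.tsv", sep="\t", index=False, float_format="%.10g"
            )
            annotation.hit_counts.to_csv(
                outdir / "annotation_hit_counts.tsv", sep="\t", index=False
            )
            counts["annotated_lncrnas"] = int(
                (annotation.per_lncrna["n_significant_sets"] > 0).sum()
            )
        else:
            counts["annotated_lncrnas"] = 0
    except Exception as exc:
        raise StageError("function_prediction", exc) from exc

    # --- stage: regulatory networks -------------------------------------------
    try:
        if loci is not None and len(edges):
            cis = find_cis_pairs(edges, loci, window=config.cis_window, mode=config.cis_mode)
        else:
            cis = find_cis_pairs(edges.iloc[:0], loci) if loci else None
        if cis is not None:
            cis.to_csv(outdir / "cis.tsv", sep="\t", index=False, float_format="%.10g")
            counts["cis_pairs"] = len(cis)
            counts.update({f"cis_{k}": v for k, v in summarize_network(cis).items()})
        if tf_collection is not None and len(edges):
            trans = find_trans_links(
                edges,
                tf_collection,
                universe,
                p_threshold=config.enrich_p_threshold,
                fdr_threshold=config.fdr_threshold,
            )
            trans.to_csv(outdir / "trans.tsv", sep="\t", index=False, float_format="%.10g")
            counts["trans_links"] = len(trans)
            two, three = build_networks(
                trans, edges, top_pairs=config.top_tf_pairs, top_core=config.top_core
            )
            write_network(two, outdir / "lncrna_tf.sif", "sif", allow_empty=True)
            write_network(three, outdir / "core_network.sif", "sif", allow_empty=True)
    except Exception as exc:
        raise StageError("regulatory_network", exc) from exc

    # --- stage: qPCR validation ------------------------------------------------
    try:
        cts = None
        if config.simulate and truth is not None and counts["de_lncrnas"] + counts["de_mrnas"] > 0:
            # validation panel: strongest DE calls, planted effects as truth
            panel = (
                sig.sort_values(["fold_change_abs", "p_value"], ascending=[False, True])
                .head(config.n_qpcr_genes)
                .index.tolist()
            )
            planted = {
                g: truth.de_features.get(g, 0) * SimConfig(**{**config.sim, "seed": config.seed}).log2_effect
                for g in panel
            }
            planted = {g: v for g, v in planted.items() if v != 0}
            if planted:
                cts = generate_qpcr_cts(
                    config.seed,
                    list(planted) + ["GAPDH"],
                    "GAPDH",
                    planted,
                    group_labels=(config.case_group, config.control_group),
                    ct_noise_sd=config.qpcr_ct_noise_sd,
                )
        elif config.cts_path:
            from .qpcr import read_ct_table

            cts = read_ct_table(config.cts_path)
        if cts is not None:
            cts.to_csv(outdir / "cts.tsv", sep="\t", index=False, float_format="%.10g")
            relquant = delta_delta_ct(cts, "GAPDH", config.case_group, config.control_group)
            relquant.to_csv(outdir / "relquant.tsv", sep="\t", float_format="%.10g")
            concordance = concordance_check(relquant, de)
            concordance.index.name = "gene_id"
            concordance.to_csv(outdir / "concordance.tsv", sep="\t", float_format="%.10g")
            counts["qpcr_genes"] = len(relquant)
            counts["qpcr_concordant"] = int(concordance["agree"].sum())
    except Exception as exc:
        raise StageError("qpcr", exc) from exc

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _manifest_config(config),
        "config_sha256": _config_hash(config),
        "counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
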