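"""End-to-end orchestration of the differential co-expression pipeline.

Stages: (optional) simulation -> differential expression/abundance ->
per-group PCIT networks -> RIF regulator scoring -> DK differential
connectivity -> cross-omics integration -> ORA / preranked GSEA with
Stouffer meta-combination.  Every stage writes plain files so each one
is independently re-runnable; a JSON manifest lists the artifacts with
row counts and the thresholds used.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from .containers import PROTEIN, TRANSCRIPT, ValidationError
from .diffexpr import (
    filter_by_expression,
    log2_normalized_counts,
    median_normalize_log2,
    moderated_t_test,
    nb_wald_test,
    significant_ids,
    size_factors,
)
from .enrich import (
    gsea_preranked,
    meta_ora,
    ora,
    rank_statistic,
    stouffer_multi_omics,
)
from .integrate import concordance, cross_omics_pairs, foldchange_correlation
from .pcit import R_CROSS, R_WITHIN, build_group_network, drop_unusable_features
from .regnet import dk_connectivity, rewiring_summary, rif_scores
from .simulate import SimulationConfig, make_gene_sets, simulate_study

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Paths, thresholds and sizes for a full pipeline run."""

    output_dir: str = "dconet_out"
    seed: int = 0
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides
    counts_path: str | None = None
    abundance_path: str | None = None
    design_path: str | None = None
    tf_list_path: str | None = None
    mapping_path: str | None = None
    gmt_path: str | None = None
    p_de: float = 0.05
    lfc_de: float = 0.5
    p_dap: float = 0.05
    r_within: float = R_WITHIN
    r_cross: float = R_CROSS
    z_cut: float = 1.96
    p_gsea: float = 0.01
    nes_cut: float = 1.5
    n_perm: int = 2000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("p_de", "lfc_de", "p_dap", "r_within", "r_cross",
                     "z_cut", "p_gsea", "nes_cut"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")
        if not self.simulate:
            for name in ("counts_path", "abundance_path", "design_path",
                         "tf_list_path", "mapping_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValidationError(f"missing input file for {name}: {p}")
        if self.gmt_path is not None and not Path(self.gmt_path).exists():
            raise ValidationError(f"GMT file not found: {self.gmt_path}")


def _write_table(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return len(df)


def _stage(name: str, t0: float, **shapes) -> None:
    desc = ", ".join(f"{k}={v}" for k, v in shapes.items())
    logger.info("stage %-12s %s (%.1fs)", name, desc, time.monotonic() - t0)


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the output manifest."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "thresholds": {k: getattr(cfg, k) for k in (
            "p_de", "lfc_de", "p_dap", "r_within", "r_cross", "z_cut",
            "p_gsea", "nes_cut")},
        "seed": cfg.seed,
        "outputs": {},
    }

    def record(key: str, path: Path, n_rows: int) -> None:
        # paths relative to the output dir: manifests from identical
        # runs into different directories stay byte-identical
        manifest["outputs"][key] = {"path": path.name, "n_rows": n_rows}

    # --- inputs ---------------------------------------------------------
    t0 = time.monotonic()
    if cfg.simulate:
        sim_cfg = SimulationConfig(**{"seed": cfg.seed, **cfg.sim})
        study = simulate_study(sim_cfg)
        fixture_dir = outdir / "inputs"
        study.write(fixture_dir)
        counts, abundance = study.counts, study.abundance
        design, tf_ids, mapping = study.design, study.tf_ids, study.mapping
        gene_sets = (dio.read_gmt(cfg.gmt_path) if cfg.gmt_path
                     else make_gene_sets(study))
        if not cfg.gmt_path:
            dio.write_gmt(gene_sets, fixture_dir / "gene_sets.gmt")
    else:
        counts = dio.read_matrix(cfg.counts_path, TRANSCRIPT)
        abundance = dio.read_matrix(cfg.abundance_path, PROTEIN)
        design = dio.read_design(cfg.design_path)
        tf_ids = dio.read_tf_list(cfg.tf_list_path)
        mapping = dio.read_mapping(cfg.mapping_path)
        gene_sets = dio.read_gmt(cfg.gmt_path) if cfg.gmt_path else None
    _stage("inputs", t0, genes=counts.shape, proteins=abundance.shape)

    # --- differential expression / abundance ---------------------------
    t0 = time.monotonic()
    filtered = filter_by_expression(counts)
    sf = size_factors(filtered)
    de_table = nb_wald_test(filtered, design, sf)
    n = _write_table(de_table, outdir / "de_genes.tsv")
    record("de_genes", outdir / "de_genes.tsv", n)

    norm_prot = median_normalize_log2(abundance)
    dap_table = moderated_t_test(norm_prot, design)
    n = _write_table(dap_table, outdir / "dap_proteins.tsv")
    record("dap_proteins", outdir / "dap_proteins.tsv", n)
    deg_ids = significant_ids(de_table)
    dap_ids = significant_ids(dap_table)
    _stage("diffexpr", t0, n_deg=len(deg_ids), n_dap=len(dap_ids))

    # --- RIF ------------------------------------------------------------
    t0 = time.monotonic()
    gene_norm = log2_normalized_counts(filtered, sf)
    expressed_tfs = [t for t in tf_ids if t in set(gene_norm.feature_ids)]
    rif_table = pd.DataFrame()
    rif_sig: list[str] = []
    if deg_ids and len(expressed_tfs) >= 3:
        rif_table = rif_scores(gene_norm, design, expressed_tfs, deg_ids)
        rif_sig = list(rif_table.loc[rif_table["significant"], "tf_id"])
        n = _write_table(rif_table, outdir / "rif_scores.tsv")
        record("rif_scores", outdir / "rif_scores.tsv", n)
    else:
        logger.warning("RIF skipped: need >=1 DEG and >=3 expressed TFs")
    _stage("rif", t0, n_tf=len(expressed_tfs), n_significant=len(rif_sig))

    # --- per-group networks and DK --------------------------------------
    networks = {}
    for layer_name, norm, anchors, r_min in (
        ("gene", gene_norm, set(deg_ids) | set(rif_sig), cfg.r_within),
        ("protein", norm_prot, set(dap_ids), cfg.r_within),
    ):
        t0 = time.monotonic()
        nets = {}
        for group in (design.reference, design.contrast):
            usable = drop_unusable_features(norm, design.samples_in(group))
            net = build_group_network(
                usable, design, group,
                anchors=anchors & set(usable.feature_ids),
                r_min=r_min, layer=layer_name,
            )
            nets[group] = net
            path = outdir / f"network_{layer_name}_{group}.tsv"
            dio.write_edge_list(net.edges, path, "tsv")
            dio.write_edge_list(net.edges,
                                outdir / f"network_{layer_name}_{group}.sif",
                                "sif")
            record(f"network_{layer_name}_{group}", path, len(net.edges))
        networks[layer_name] = nets

        dk = dk_connectivity(nets[design.reference], nets[design.contrast])
        n = _write_table(dk, outdir / f"dk_{layer_name}.tsv")
        record(f"dk_{layer_name}", outdir / f"dk_{layer_name}.tsv", n)

        rewiring = rewiring_summary(nets[design.reference],
                                    nets[design.contrast])
        rpath = outdir / f"rewiring_{layer_name}.json"
        rpath.write_text(json.dumps(rewiring, indent=2, sort_keys=True))
        record(f"rewiring_{layer_name}", rpath, rewiring["n_edges_shared"])
        _stage(f"network_{layer_name}", t0,
               edges_fertile=len(nets[design.reference].edges),
               edges_subfertile=len(nets[design.contrast].edges))

    # --- cross-omics integration ----------------------------------------
    t0 = time.monotonic()
    pairs = dio.match_cross_layer(counts, abundance, mapping)
    de_index = set(de_table["feature_id"])
    dap_index = set(dap_table["feature_id"])
    stat_pairs = [(g, p) for g, p in pairs
                  if g in de_index and p in dap_index]
    integration: dict = {"n_matched_pairs": len(stat_pairs)}
    if len(stat_pairs) >= 3:
        quadrants, summary = concordance(stat_pairs, de_table, dap_table)
        n = _write_table(quadrants, outdir / "quadrants.tsv")
        record("quadrants", outdir / "quadrants.tsv", n)
        r, p_r = foldchange_correlation(stat_pairs, de_table, dap_table)
        integration.update(summary)
        integration["foldchange_r"] = r
        integration["foldchange_p"] = p_r

    prot_complete = drop_unusable_features(norm_prot, norm_prot.sample_ids)
    cross_anchors = set(deg_ids) | set(dap_ids)
    xnets, xsummary = cross_omics_pairs(
        gene_norm, prot_complete, design,
        anchors=cross_anchors, r_min=cfg.r_cross)
    for group, net in xnets.items():
        path = outdir / f"network_cross_{group}.tsv"
        dio.write_edge_list(net.edges, path, "tsv")
        record(f"network_cross_{group}", path, len(net.edges))
    integration["cross_omics"] = xsummary
    ipath = outdir / "integration.json"
    ipath.write_text(json.dumps(integration, indent=2, sort_keys=True))
    record("integration", ipath, len(stat_pairs))
    _stage("integrate", t0, pairs=len(stat_pairs),
           cross_edges=sum(len(n.edges) for n in xnets.values()))

    # --- enrichment ------------------------------------------------------
    if gene_sets is not None and len(gene_sets):
        t0 = time.monotonic()
        gene_bg = list(de_table["feature_id"])
        prot_bg_genes = sorted({mapping.get(p, p) for p in dap_table["feature_id"]})
        mapped_dap = sorted({mapping.get(p, p) for p in dap_ids})
        ora_gene = ora(deg_ids, gene_bg, gene_sets) if deg_ids else pd.DataFrame()
        ora_prot = (ora(mapped_dap, prot_bg_genes, gene_sets)
                    if mapped_dap else pd.DataFrame())
        if not ora_gene.empty:
            n = _write_table(ora_gene, outdir / "ora_genes.tsv")
            record("ora_genes", outdir / "ora_genes.tsv", n)
        if not ora_prot.empty:
            n = _write_table(ora_prot, outdir / "ora_proteins.tsv")
            record("ora_proteins", outdir / "ora_proteins.tsv", n)
        if not ora_gene.empty and not ora_prot.empty:
            meta = meta_ora(ora_gene, ora_prot)
            n = _write_table(meta, outdir / "ora_meta.tsv")
            record("ora_meta", outdir / "ora_meta.tsv", n)

        ranked_gene = rank_statistic(de_table)
        gsea_gene = gsea_preranked(ranked_gene, gene_sets,
                                   n_perm=cfg.n_perm, seed=cfg.seed + 10)
        n = _write_table(gsea_gene, outdir / "gsea_genes.tsv")
        record("gsea_genes", outdir / "gsea_genes.tsv", n)

        prot_stats = dap_table.copy()
        prot_stats["feature_id"] = [mapping.get(p, p)
                                    for p in prot_stats["feature_id"]]
        prot_stats = prot_stats.drop_duplicates("feature_id")
        ranked_prot = rank_statistic(prot_stats)
        gsea_prot = gsea_preranked(ranked_prot, gene_sets,
                                   n_perm=cfg.n_perm, seed=cfg.seed + 11)
        n = _write_table(gsea_prot, outdir / "gsea_proteins.tsv")
        record("gsea_proteins", outdir / "gsea_proteins.tsv", n)

        if not gsea_gene.empty and not gsea_prot.empty:
            combined = stouffer_multi_omics(gsea_gene, gsea_prot)
            n = _write_table(combined, outdir / "gsea_combined.tsv")
            record("gsea_combined", outdir / "gsea_combined.tsv", n)
        _stage("enrich", t0, n_sets=len(gene_sets))

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
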