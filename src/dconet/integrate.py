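"""Transcriptome-proteome integration.

Matched gene-protein pairs are compared on their log2 fold changes:
sign-based concordance counts, a nine-quadrant (3x3) classification
with +/-0.5 log2FC boundaries, and the Pearson correlation of fold
changes.  Cross-layer co-expression runs PCIT on the stacked
gene+protein matrix per phenotype group and reports only
heterolayer edges.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    CROSS_OMICS,
    ExpressionMatrix,
    PcitNetwork,
    SampleDesign,
    ValidationError,
)
from .pcit import R_CROSS, build_group_network, drop_unusable_features
from .regnet import rewiring_summary

logger = logging.getLogger(__name__)

QUADRANT_BOUNDARY = 0.5


def _band(lfc: float, boundary: float) -> str:
    if lfc >= boundary:
        return "up"
    if lfc <= -boundary:
        return "down"
    return "neutral"


def concordance(
    pairs: list[tuple[str, str]],
    gene_stats: pd.DataFrame,
    prot_stats: pd.DataFrame,
    boundary: float = QUADRANT_BOUNDARY,
) -> tuple[pd.DataFrame, dict]:
    """Nine-quadrant table and concordance summary for matched pairs.

    The grid uses +/-``boundary`` log2FC thresholds on each axis; the
    concordance counts are sign-based (up-up, down-down concordant;
    mixed signs discordant) with exact-zero fold changes excluded.
    """
    g = gene_stats.set_index("feature_id")
    p = prot_stats.set_index("feature_id")
    rows = []
    for gene, prot in pairs:
        if gene not in g.index:
            raise ValidationError(f"pair gene {gene!r} missing from gene stats")
        if prot not in p.index:
            raise ValidationError(f"pair protein {prot!r} missing from protein stats")
        glfc = float(g.at[gene, "log2fc"])
        plfc = float(p.at[prot, "log2fc"])
        gsig = bool(g.at[gene, "significant"])
        psig = bool(p.at[prot, "significant"])
        sig_class = {
            (True, True): "both",
            (True, False): "deg_only",
            (False, True): "dap_only",
            (False, False): "neither",
        }[(gsig, psig)]
        rows.append({
            "gene_id": gene,
            "protein_id": prot,
            "gene_log2fc": glfc,
            "protein_log2fc": plfc,
            "gene_band": _band(glfc, boundary),
            "protein_band": _band(plfc, boundary),
            "significance": sig_class,
        })
    table = pd.DataFrame(rows, columns=[
        "gene_id", "protein_id", "gene_log2fc", "protein_log2fc",
        "gene_band", "protein_band", "significance",
    ])

    grid: dict[str, int] = {}
    for gb in ("down", "neutral", "up"):
        for pb in ("down", "neutral", "up"):
            grid[f"{gb}_{pb}"] = 0
    signed = {"up_up": 0, "down_down": 0, "up_down": 0, "down_up": 0}
    for row in rows:
        grid[f"{row['gene_band']}_{row['protein_band']}"] += 1
        gs, ps = np.sign(row["gene_log2fc"]), np.sign(row["protein_log2fc"])
        if gs == 0 or ps == 0:
            continue
        key = f"{'up' if gs > 0 else 'down'}_{'up' if ps > 0 else 'down'}"
        signed[key] += 1
    summary = {
        "n_pairs": len(rows),
        "grid": grid,
        "sign_counts": signed,
        "n_concordant": signed["up_up"] + signed["down_down"],
        "n_discordant": signed["up_down"] + signed["down_up"],
    }
    return table, summary


def foldchange_correlation(
    pairs: list[tuple[str, str]],
    gene_stats: pd.DataFrame,
    prot_stats: pd.DataFrame,
) -> tuple[float, float]:
    """Pearson correlation (and t-test p) between gene and protein
    log2 fold changes over the matched pairs."""
    if len(pairs) < 3:
        raise ValidationError("fold-change correlation needs >= 3 pairs")
    g = gene_stats.set_index("feature_id")["log2fc"]
    p = prot_stats.set_index("feature_id")["log2fc"]
    x = np.array([g[gene] for gene, _ in pairs], dtype=float)
    y = np.array([p[prot] for _, prot in pairs], dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero variance in fold changes; r undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def cross_omics_pairs(
    gene_norm: ExpressionMatrix,
    prot_norm: ExpressionMatrix,
    design: SampleDesign,
    anchors: set[str],
    r_min: float = R_CROSS,
) -> tuple[dict[str, PcitNetwork], dict]:
    """Cross-layer co-expression networks per phenotype group.

    PCIT runs on the stacked gene+protein matrix of each group; only
    gene-protein (heterolayer) edges passing the p <= 0.05,
    |r| >= ``r_min`` and anchor (DEG-or-DAP endpoint) filters are
    reported.  Returns the per-group networks and a shared-pair /
    sign-flip summary.
    """
    if set(gene_norm.sample_ids) != set(prot_norm.sample_ids):
        raise ValidationError("gene and protein layers cover different samples")
    samples = gene_norm.sample_ids
    overlap = set(gene_norm.feature_ids) & set(prot_norm.feature_ids)
    if overlap:
        raise ValidationError(f"feature IDs shared across layers: {sorted(overlap)[:5]}")
    stacked = ExpressionMatrix(
        pd.concat([gene_norm.data, prot_norm.data[samples]]), gene_norm.layer
    )
    gene_ids = set(gene_norm.feature_ids)

    networks: dict[str, PcitNetwork] = {}
    for group in (design.reference, design.contrast):
        usable = drop_unusable_features(stacked, design.samples_in(group))
        present_anchors = anchors & set(usable.feature_ids)
        net = build_group_network(
            usable, design, group,
            anchors=present_anchors, r_min=r_min, layer=CROSS_OMICS,
        )
        hetero = net.edges[
            net.edges["feature_a"].isin(gene_ids)
            != net.edges["feature_b"].isin(gene_ids)
        ].reset_index(drop=True)
        networks[group] = PcitNetwork(
            group=group, layer=CROSS_OMICS, edges=hetero,
            n_features=net.n_features,
            n_pcit_retained=net.n_pcit_retained,
            n_p_significant=net.n_p_significant,
        )
    summary = rewiring_summary(networks[design.reference],
                               networks[design.contrast])
    return networks, summary
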