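"""Differential-regulation statistics on the group networks.

* RIF1/RIF2 regulatory impact factors: rank transcription factors by
  how differently they co-express with the differentially expressed
  targets between the two phenotype groups (RIF1) and by how well
  their group-specific correlations weight target abundance (RIF2).
* DK differential connectivity: per-node difference in max-normalized
  degree between the two group networks, with z-score significance.
* A rewiring summary: node/edge overlap between the group networks and
  correlation sign flips on shared edges.

Significance for both RIF and DK uses the two-sided standard-normal
cutoff |z| >= 1.96 (p <= 0.05).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PcitNetwork, SampleDesign, ValidationError

logger = logging.getLogger(__name__)

Z_CUTOFF = 1.96


def _group_corr_and_means(
    norm: ExpressionMatrix, samples: list[str], tf_ids: list[str], de_ids: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-group TF x DE-target correlations, DE means and TF SDs."""
    data = norm.data[samples]
    tf = data.loc[tf_ids].to_numpy(dtype=float)
    de = data.loc[de_ids].to_numpy(dtype=float)
    tf_c = tf - tf.mean(axis=1, keepdims=True)
    de_c = de - de.mean(axis=1, keepdims=True)
    tf_sd = tf_c.std(axis=1)
    de_sd = de_c.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (tf_c @ de_c.T) / len(samples) / np.outer(tf_sd, de_sd)
    r = np.clip(r, -1.0, 1.0)
    return r, de.mean(axis=1), tf_sd


def rif_scores(
    norm: ExpressionMatrix,
    design: SampleDesign,
    tf_ids: list[str],
    de_ids: list[str],
) -> pd.DataFrame:
    """RIF1/RIF2 scores for candidate regulators.

    With per-group correlations r1/r2 (group 1 = fertile reference,
    group 2 = subfertile contrast) between TF i and DE target j, and
    per-group mean normalized expression e1_j/e2_j of the targets:

        PIF_j  = 1/2 (e1_j + e2_j)(e1_j - e2_j)
        RIF1_i = mean_j PIF_j (r1_ij - r2_ij)^2
        RIF2_i = mean_j [(e1_j r1_ij)^2 - (e2_j r2_ij)^2]

    Each metric is z-standardized over the scored TFs; a TF is flagged
    when either |z| >= 1.96.  TFs with zero variance in either group
    are excluded; at least 3 scorable TFs are required.
    """
    tf_ids = [t for t in tf_ids if t in set(norm.feature_ids)]
    de_ids = [d for d in de_ids if d in set(norm.feature_ids)]
    if not de_ids:
        raise ValidationError("RIF needs at least one DE target")

    s1 = design.samples_in(design.reference)
    s2 = design.samples_in(design.contrast)
    r1, e1, sd1 = _group_corr_and_means(norm, s1, tf_ids, de_ids)
    r2, e2, sd2 = _group_corr_and_means(norm, s2, tf_ids, de_ids)

    usable = (sd1 > 0) & (sd2 > 0)
    dropped = [t for t, u in zip(tf_ids, usable) if not u]
    if dropped:
        logger.info("RIF: excluded %d zero-variance TFs", len(dropped))
    tf_ids = [t for t, u in zip(tf_ids, usable) if u]
    if len(tf_ids) < 3:
        raise ValidationError("RIF z-scores need at least 3 scorable TFs")
    r1, r2 = r1[usable], r2[usable]

    pif = 0.5 * (e1 + e2) * (e1 - e2)
    rif1 = np.mean(pif[None, :] * (r1 - r2) ** 2, axis=1)
    rif2 = np.mean((e1[None, :] * r1) ** 2 - (e2[None, :] * r2) ** 2, axis=1)

    def zscore(x: np.ndarray) -> np.ndarray:
        sd = np.std(x, ddof=1)
        if sd == 0:
            return np.zeros_like(x)
        return (x - np.mean(x)) / sd

    rif1_z = zscore(rif1)
    rif2_z = zscore(rif2)
    return pd.DataFrame({
        "tf_id": tf_ids,
        "rif1_raw": rif1,
        "rif2_raw": rif2,
        "rif1_z": rif1_z,
        "rif2_z": rif2_z,
        "significant": (np.abs(rif1_z) >= Z_CUTOFF) | (np.abs(rif2_z) >= Z_CUTOFF),
    })


def dk_connectivity(
    net_fertile: PcitNetwork, net_subfertile: PcitNetwork
) -> pd.DataFrame:
    """Differential connectivity DK_i = K_fertile,i - K_subfertile,i.

    K is the node degree normalized by the maximum degree of its
    network; nodes absent from a network have degree 0.  dk is
    z-standardized over the node universe and flagged at |z| >= 1.96.
    """
    deg_f = net_fertile.degrees()
    deg_s = net_subfertile.degrees()
    universe = sorted(set(deg_f.index) | set(deg_s.index))
    if not universe:
        return pd.DataFrame(columns=[
            "feature_id", "degree_fertile", "degree_subfertile",
            "k_fertile", "k_subfertile", "dk", "dk_z", "significant",
        ])
    df = pd.DataFrame(index=universe)
    df["degree_fertile"] = deg_f.reindex(universe).fillna(0).astype(int)
    df["degree_subfertile"] = deg_s.reindex(universe).fillna(0).astype(int)
    for col, knorm in (("degree_fertile", "k_fertile"),
                       ("degree_subfertile", "k_subfertile")):
        kmax = df[col].max()
        if kmax == 0:
            logger.warning("empty network: all %s set to 0", knorm)
            df[knorm] = 0.0
        else:
            df[knorm] = df[col] / kmax
    df["dk"] = df["k_fertile"] - df["k_subfertile"]
    sd = df["dk"].std(ddof=1)
    df["dk_z"] = 0.0 if sd == 0 else (df["dk"] - df["dk"].mean()) / sd
    df["significant"] = df["dk_z"].abs() >= Z_CUTOFF
    df = df.reset_index(names="feature_id")
    return df


def rewiring_summary(net_a: PcitNetwork, net_b: PcitNetwork) -> dict:
    """Node/edge overlap between two networks and correlation sign
    flips (r_a * r_b < 0) on the shared edges."""
    nodes_a, nodes_b = net_a.nodes(), net_b.nodes()
    edges_a, edges_b = net_a.edge_keys(), net_b.edge_keys()
    shared_edges = edges_a & edges_b

    ra = dict(zip(zip(net_a.edges["feature_a"], net_a.edges["feature_b"]),
                  net_a.edges["r"]))
    rb = dict(zip(zip(net_b.edges["feature_a"], net_b.edges["feature_b"]),
                  net_b.edges["r"]))
    flipped = sorted(e for e in shared_edges if ra[e] * rb[e] < 0)

    return {
        "n_nodes_a": len(nodes_a),
        "n_nodes_b": len(nodes_b),
        "n_nodes_shared": len(nodes_a & nodes_b),
        "n_nodes_only_a": len(nodes_a - nodes_b),
        "n_nodes_only_b": len(nodes_b - nodes_a),
        "n_edges_a": len(edges_a),
        "n_edges_b": len(edges_b),
        "n_edges_shared": len(shared_edges),
        "n_sign_flipped": len(flipped),
        "sign_flipped_pairs": [list(e) for e in flipped],
    }
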