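"""Over-representation analysis and preranked gene set enrichment.

ORA is a hypergeometric upper-tail test of a hit list against gene
sets within a declared background; hit lists from the two omics layers
can be meta-combined per set with Stouffer's method.

Preranked GSEA ranks features by sign(log2FC) * -log10(p), computes a
weighted Kolmogorov-Smirnov-style running-sum enrichment score (weight
exponent 1), calibrates it against gene-label permutations, and
combines the per-layer results across omics layers with a directional
Stouffer test.  Significance follows p <= 0.01 and |NES| >= 1.5.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)

GSEA_P_CUTOFF = 0.01
NES_CUTOFF = 1.5
P_FLOOR = 1e-300
MIN_SET_SIZE = 5
MAX_SET_SIZE = 500


def rank_statistic(stats_table: pd.DataFrame) -> pd.Series:
    """Ranking statistic sign(log2FC) * -log10(p), sorted descending.

    p is floored at 1e-300; a zero fold change gives statistic 0.
    Ties are broken by feature ID so the ordering is deterministic.
    """
    p = np.clip(stats_table["p"].to_numpy(dtype=float), P_FLOOR, 1.0)
    stat = np.sign(stats_table["log2fc"].to_numpy(dtype=float)) * (-np.log10(p))
    ranked = pd.Series(stat, index=stats_table["feature_id"].astype(str).values)
    order = sorted(ranked.index, key=lambda f: (-ranked[f], f))
    return ranked.loc[order]


def ora(
    list_ids, background_ids, sets: GeneSetCollection
) -> pd.DataFrame:
    """Hypergeometric over-representation of a hit list in each set.

    p = P(X >= k) with k = |list & set|, K = |set & background|,
    n = |list|, N = |background|; sets disjoint from the background
    are skipped with a warning.
    """
    hits = set(list_ids)
    background = set(background_ids)
    offenders = hits - background
    if offenders:
        raise ValidationError(
            f"hit list not contained in background: {sorted(offenders)[:5]}"
        )
    N, n = len(background), len(hits)
    rows = []
    for name, members in sets:
        in_bg = set(members) & background
        K = len(in_bg)
        if K == 0:
            logger.warning("set %r disjoint from background; skipped", name)
            continue
        k = len(in_bg & hits)
        # hypergeom.sf(k-1) = P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "set_name": name, "overlap": k, "set_size": K,
            "list_size": n, "background_size": N,
            "p_hyper": min(max(p, P_FLOOR), 1.0),
        })
    return pd.DataFrame(rows, columns=[
        "set_name", "overlap", "set_size", "list_size",
        "background_size", "p_hyper",
    ])


def stouffer_combine(pvals: list[float]) -> float:
    """One-sided Stouffer combination: z_i = Phi^-1(1 - p_i),
    combined z = sum(z)/sqrt(k), meta-p = 1 - Phi(z)."""
    z = stats.norm.isf(np.clip(pvals, P_FLOOR, 1 - 1e-16))
    combined = float(np.sum(z) / np.sqrt(len(z)))
    return float(np.clip(stats.norm.sf(combined), P_FLOOR, 1.0))


def meta_ora(ora_gene: pd.DataFrame, ora_protein: pd.DataFrame) -> pd.DataFrame:
    """Stouffer meta-combination of gene- and protein-layer ORA
    p-values per set; single-layer sets keep their own p, flagged."""
    g = ora_gene.set_index("set_name")
    p = ora_protein.set_index("set_name")
    names = list(dict.fromkeys(list(g.index) + list(p.index)))
    rows = []
    for name in names:
        in_g, in_p = name in g.index, name in p.index
        if in_g and in_p:
            meta_p = stouffer_combine([g.at[name, "p_hyper"],
                                       p.at[name, "p_hyper"]])
            layers = "both"
        else:
            meta_p = float(g.at[name, "p_hyper"] if in_g else p.at[name, "p_hyper"])
            layers = "gene_only" if in_g else "protein_only"
        rows.append({
            "set_name": name,
            "p_gene": float(g.at[name, "p_hyper"]) if in_g else np.nan,
            "p_protein": float(p.at[name, "p_hyper"]) if in_p else np.nan,
            "meta_p": meta_p,
            "layers": layers,
        })
    return pd.DataFrame(rows)


def enrichment_score(stat: np.ndarray, hit_mask: np.ndarray) -> float:
    """Weighted running-sum enrichment score (weight exponent 1).

    ``stat`` is the descending ranking statistic; hits increment the
    sum by |stat|/sum(|stat| over hits), misses decrement by
    1/(N - n_hits); ES is the extremum of the running sum.
    """
    n = len(stat)
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits == n:
        raise ValidationError("hit set must be a proper non-empty subset")
    w = np.abs(stat) * hit_mask
    total = w.sum()
    if total == 0:
        raise ValidationError("zero total |stat| among hits")
    steps = np.where(hit_mask, w / total, -1.0 / (n - n_hits))
    running = np.cumsum(steps)
    pos, neg = float(running.max()), float(running.min())
    return pos if pos >= -neg else neg


def gsea_preranked(
    ranked: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 10000,
    seed: int = 0,
    min_size: int = MIN_SET_SIZE,
    max_size: int = MAX_SET_SIZE,
) -> pd.DataFrame:
    """Preranked GSEA with gene-label permutation nulls.

    For each eligible set: ES from the running sum; a null ES
    distribution from ``n_perm`` random same-size hit sets (gene-label
    permutation); NES = ES / mean(|null ES| of same-sign nulls);
    p_perm = fraction of same-sign nulls at least as extreme, floored
    at 1/n_perm.
    """
    stat = ranked.to_numpy(dtype=float)
    if not np.isfinite(stat).all():
        raise ValidationError("ranking statistics must be finite")
    ids = np.asarray(ranked.index)
    id_pos = {f: i for i, f in enumerate(ids)}
    n = len(ids)
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in sets:
        pos = sorted(id_pos[m] for m in members if m in id_pos)
        k = len(pos)
        if k < min_size or k > max_size or k == n:
            continue
        hit = np.zeros(n, dtype=bool)
        hit[pos] = True
        if np.abs(stat[hit]).sum() == 0:
            logger.warning("set %r has zero total |stat| among hits; skipped", name)
            continue
        es = enrichment_score(stat, hit)

        null_es = np.empty(n_perm)
        for b in range(n_perm):
            perm_hit = np.zeros(n, dtype=bool)
            perm_hit[rng.choice(n, size=k, replace=False)] = True
            if np.abs(stat[perm_hit]).sum() == 0:
                null_es[b] = 0.0
            else:
                null_es[b] = enrichment_score(stat, perm_hit)

        same_sign = null_es * np.sign(es) > 0
        if same_sign.any():
            denom = np.mean(np.abs(null_es[same_sign]))
            nes = es / denom if denom > 0 else 0.0
            p_perm = float(
                np.sum(np.abs(null_es[same_sign]) >= abs(es)) / same_sign.sum()
            )
        else:
            nes = 0.0
            p_perm = 0.0
        p_perm = max(p_perm, 1.0 / n_perm)
        rows.append({
            "set_name": name, "size": k, "es": es, "nes": float(nes),
            "p_perm": float(p_perm),
        })
    df = pd.DataFrame(rows, columns=["set_name", "size", "es", "nes", "p_perm"])
    if not df.empty:
        df["significant"] = (df["p_perm"] <= GSEA_P_CUTOFF) & (
            df["nes"].abs() >= NES_CUTOFF
        )
    else:
        df["significant"] = pd.Series(dtype=bool)
    return df


def stouffer_multi_omics(
    gene_res: pd.DataFrame, prot_res: pd.DataFrame
) -> pd.DataFrame:
    """Directional Stouffer combination of per-layer GSEA results.

    Per layer z_i = sign(NES_i) * Phi^-1(1 - p_i/2); combined
    z = sum(z_i)/sqrt(k) over the layers containing the set; combined
    two-sided p = 2(1 - Phi(|z|)).  The significance flag applies the
    p <= 0.01 and |NES| >= 1.5 thresholds to the combined p and the
    layer NES of largest magnitude.
    """
    g = gene_res.set_index("set_name")
    p = prot_res.set_index("set_name")
    names = list(dict.fromkeys(list(g.index) + list(p.index)))
    rows = []
    for name in names:
        zs, ness = [], []
        for layer in (g, p):
            if name in layer.index:
                p_layer = float(np.clip(layer.at[name, "p_perm"], P_FLOOR, 1.0))
                nes = float(layer.at[name, "nes"])
                zs.append(np.sign(nes) * stats.norm.isf(p_layer / 2))
                ness.append(nes)
        combined_z = float(np.sum(zs) / np.sqrt(len(zs)))
        combined_p = float(np.clip(2 * stats.norm.sf(abs(combined_z)), P_FLOOR, 1.0))
        nes_extreme = max(ness, key=abs)
        rows.append({
            "set_name": name,
            "nes_gene": float(g.at[name, "nes"]) if name in g.index else np.nan,
            "nes_protein": float(p.at[name, "nes"]) if name in p.index else np.nan,
            "combined_z": combined_z,
            "combined_p": combined_p,
            "significant": combined_p <= GSEA_P_CUTOFF
            and abs(nes_extreme) >= NES_CUTOFF,
        })
    return pd.DataFrame(rows)
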