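"""Partial Correlation and Information Theory (PCIT) edge selection.

For every trio of features (x, y, z) the three first-order partial
correlations are computed and averaged into a data-driven local
tolerance; an edge whose correlation can be explained through some
third feature (it falls below the tolerance-scaled correlations of
both legs of the detour) is flagged non-significant.  Edges that no
trio eliminates are kept.

The selected edges are then subjected to the study's post-hoc filters:
a t-test on the correlation (p <= 0.05), a hard |r| threshold, and an
anchor rule requiring at least one differentially expressed / scored
feature per edge.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ExpressionMatrix,
    PcitNetwork,
    SampleDesign,
    ValidationError,
    edge_frame,
)

logger = logging.getLogger(__name__)

EDGE_P_CUTOFF = 0.05
R_WITHIN = 0.95
R_CROSS = 0.90


def pearson_matrix(matrix: ExpressionMatrix, sample_ids=None) -> pd.DataFrame:
    """Pairwise Pearson correlation over the given samples.

    Zero-variance features must be removed beforehand; reaching this
    operation with one is an error.
    """
    data = matrix.data if sample_ids is None else matrix.data[list(sample_ids)]
    values = data.to_numpy(dtype=float)
    if values.shape[1] < 3:
        raise ValidationError("correlation needs at least 3 samples")
    if np.isnan(values).any():
        raise ValidationError("missing values reached correlation")
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = [f for f, s in zip(data.index, sd) if s == 0]
        raise ValidationError(f"zero-variance features: {bad[:5]}")
    r = np.corrcoef(values)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=data.index, columns=data.index)


def partial_correlation(rxy: float, rxz: float, ryz: float) -> float:
    """First-order partial correlation of x and y given z."""
    if abs(rxz) >= 1 or abs(ryz) >= 1:
        raise ValidationError("degenerate conditioning: |r| = 1")
    return (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))


def pcit_select(corr: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Boolean keep-matrix of PCIT-significant edges.

    For each trio the local tolerance is the mean of the three ratios
    |partial r| / |r| (a ratio with zero denominator contributes 0);
    the edge (x, y) is eliminated if, for some z, |r_xy| is at or below
    the tolerance-scaled |r_xz| and |r_yz|.  With fewer than three
    features every edge is kept.
    """
    R = np.asarray(corr, dtype=float)
    n = R.shape[0]
    keep = np.ones((n, n), dtype=bool)
    np.fill_diagonal(keep, False)
    if n < 3:
        if n == 2:
            logger.warning("PCIT with %d features: no trios, all edges kept", n)
        return keep

    absR = np.abs(R)
    sqrt1m = np.sqrt(np.clip(1.0 - R * R, 0.0, None))
    eliminated = np.zeros((n, n), dtype=bool)
    # reusable work buffers: the trio loop is allocation-bound otherwise
    w1 = np.empty((n, n))
    w2 = np.empty((n, n))
    eps = np.empty((n, n))
    b1 = np.empty((n, n), dtype=bool)
    b2 = np.empty((n, n), dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        for z in range(n):
            rz = R[:, z]
            arz = absR[:, z]
            s = sqrt1m[:, z]  # sqrt(1 - r_.z^2)

            # t1 = |r_xy.z| / |r_xy|
            np.outer(rz, rz, out=w1)
            np.subtract(R, w1, out=w1)
            np.abs(w1, out=w1)
            np.outer(s, s, out=w2)
            np.divide(w1, w2, out=w1)
            np.divide(w1, absR, out=w1)
            w1[absR == 0] = 0.0
            np.copyto(eps, w1)

            # t2 = |r_xz.y| / |r_xz|
            np.multiply(R, rz[None, :], out=w1)
            np.subtract(rz[:, None], w1, out=w1)
            np.abs(w1, out=w1)
            np.multiply(sqrt1m, s[None, :], out=w2)
            np.divide(w1, w2, out=w1)
            np.divide(w1, arz[:, None], out=w1)
            w1[arz == 0, :] = 0.0
            eps += w1

            # t3 = |r_yz.x| / |r_yz|
            np.multiply(R, rz[:, None], out=w1)
            np.subtract(rz[None, :], w1, out=w1)
            np.abs(w1, out=w1)
            np.multiply(sqrt1m, s[:, None], out=w2)
            np.divide(w1, w2, out=w1)
            np.divide(w1, arz[None, :], out=w1)
            w1[:, arz == 0] = 0.0
            eps += w1
            eps *= 1.0 / 3.0

            # eliminate (x, y) when |r_xy| <= eps|r_xz| and <= eps|r_yz|
            np.multiply(eps, arz[:, None], out=w1)
            np.multiply(eps, arz[None, :], out=w2)
            np.less_equal(absR, w1, out=b1)
            np.less_equal(absR, w2, out=b2)
            b1 &= b2
            b1[z, :] = False
            b1[:, z] = False
            np.fill_diagonal(b1, False)
            eliminated |= b1

    keep &= ~(eliminated | eliminated.T)
    return keep


def edge_significance(r: np.ndarray | float, n: int) -> np.ndarray | float:
    """Two-sided p for a Pearson correlation via the t-test on n-2 df."""
    if n < 3:
        raise ValidationError("edge significance needs n >= 3")
    r_arr = np.asarray(r, dtype=float)
    p = np.ones_like(r_arr)
    at_one = np.abs(r_arr) >= 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_arr * np.sqrt((n - 2) / (1 - r_arr**2))
    p = np.where(at_one, 0.0, 2 * stats.t.sf(np.abs(t), n - 2))
    return p if np.ndim(r) else float(p)


def drop_unusable_features(
    matrix: ExpressionMatrix, sample_ids
) -> ExpressionMatrix:
    """Remove features with missing values or zero variance over the
    given samples (they cannot enter a correlation network)."""
    data = matrix.data[list(sample_ids)]
    values = data.to_numpy(dtype=float)
    usable = ~np.isnan(values).any(axis=1)
    usable &= np.nanstd(values, axis=1) > 0
    return ExpressionMatrix(matrix.data.loc[usable], matrix.layer)


def build_group_network(
    norm: ExpressionMatrix,
    design: SampleDesign,
    group: str,
    anchors: set[str],
    r_min: float = R_WITHIN,
    layer: str | None = None,
    corr: pd.DataFrame | None = None,
    keep: np.ndarray | None = None,
) -> PcitNetwork:
    """PCIT network for one phenotype group with the post-hoc filters.

    An edge is retained iff it is PCIT-significant, its correlation
    t-test gives p <= 0.05, |r| >= ``r_min``, and at least one endpoint
    is an anchor (DEG/RIF for genes, DAP for proteins).  Precomputed
    ``corr``/``keep`` may be passed to share work across calls.
    """
    if not 0 < r_min < 1:
        raise ValidationError("r_min must be in (0, 1)")
    layer = layer or norm.layer
    samples = design.samples_in(group)
    clean = drop_unusable_features(norm, samples)
    unknown = anchors - set(norm.feature_ids)
    if unknown:
        raise ValidationError(f"anchors not in matrix: {sorted(unknown)[:5]}")
    if not anchors:
        logger.warning("empty anchor set: network for %s will be empty", group)

    if corr is None:
        corr = pearson_matrix(clean, samples)
    R = corr.to_numpy()
    n_samp = len(samples)
    if keep is None:
        keep = pcit_select(R)
    p = edge_significance(R, n_samp)

    ids = np.asarray(corr.index)
    iu = np.triu_indices(len(ids), k=1)
    kept_u = keep[iu]
    p_u = p[iu]
    r_u = R[iu]
    n_pcit = int(kept_u.sum())
    n_sig = int(((p_u <= EDGE_P_CUTOFF) & kept_u).sum())

    anchor_mask = np.isin(ids, list(anchors))
    has_anchor = anchor_mask[iu[0]] | anchor_mask[iu[1]]
    final = kept_u & (p_u <= EDGE_P_CUTOFF) & (np.abs(r_u) >= r_min) & has_anchor

    records = [
        (ids[i], ids[j], r, group, layer)
        for i, j, r in zip(iu[0][final], iu[1][final], r_u[final])
    ]
    return PcitNetwork(
        group=group,
        layer=layer,
        edges=edge_frame(records),
        n_features=len(ids),
        n_pcit_retained=n_pcit,
        n_p_significant=n_sig,
    )
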