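"""Differential expression and differential abundance tests.

Transcripts: counts-per-million expression filter, median-of-ratios
size factors, and a simplified negative-binomial Wald test (moment
dispersion, no shrinkage).  Proteins: log2 + median normalization and
an empirical-Bayes moderated t-test.  Both branches produce the same
per-feature statistics table and share the significance classifier:

* gene (DEG):    p <= 0.05 and |log2FC| >= 0.5
* protein (DAP): p <= 0.05

Fold changes are contrast-over-reference (subfertile/fertile); the
direction label ("up"/"down") refers to the subfertile group.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import (
    NORMALIZED,
    PROTEIN,
    TRANSCRIPT,
    ExpressionMatrix,
    SampleDesign,
    ValidationError,
)

logger = logging.getLogger(__name__)

P_CUTOFF = 0.05
LFC_CUTOFF = 0.5
PSEUDOCOUNT = 0.5

STAT_COLUMNS = [
    "feature_id", "base_mean", "log2fc", "se", "stat", "p", "q",
    "significant", "direction",
]


def filter_by_expression(
    counts: ExpressionMatrix, min_cpm: float = 10.0, min_frac: float = 0.7
) -> ExpressionMatrix:
    """Keep genes with CPM >= ``min_cpm`` in at least
    ``ceil(min_frac * n_samples)`` samples."""
    values = counts.values()
    libsize = values.sum(axis=0)
    if (libsize <= 0).any():
        raise ValidationError("sample with zero library size")
    cpm = 1e6 * values / libsize
    n_needed = math.ceil(min_frac * values.shape[1])
    keep = (cpm >= min_cpm).sum(axis=1) >= n_needed
    if not keep.any():
        logger.warning("expression filter removed every feature")
    return ExpressionMatrix(counts.data.loc[keep], counts.layer)


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only features positive in every sample contribute to the median;
    if none exist, library-size ratios are used instead.
    """
    values = counts.values()
    all_positive = (values > 0).all(axis=1)
    if all_positive.any():
        sub = values[all_positive]
        log_geomean = np.mean(np.log(sub), axis=1)
        ratios = sub / np.exp(log_geomean)[:, None]
        sf = np.median(ratios, axis=0)
    else:
        logger.warning("no feature positive in all samples; "
                       "falling back to library-size factors")
        lib = values.sum(axis=0)
        sf = lib / np.exp(np.mean(np.log(lib)))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.sample_ids, name="size_factor")


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def nb_wald_test(
    counts: ExpressionMatrix, design: SampleDesign, sf: pd.Series
) -> pd.DataFrame:
    """Simplified negative-binomial Wald test per gene.

    Counts are scaled by the size factors; a per-gene moment estimate
    of the NB dispersion is pooled across the two groups; the Wald
    statistic is log2FC over its delta-method standard error, referred
    to a t distribution on n_A + n_B - 2 df (the moment dispersion is
    itself estimated from the same few samples, and the small-sample t
    reference keeps the test calibrated at n = 6 per group where the
    asymptotic normal reference is anti-conservative).
    """
    values = counts.values() / sf.loc[counts.sample_ids].to_numpy()
    ref = np.isin(counts.sample_ids, design.samples_in(design.reference))
    con = np.isin(counts.sample_ids, design.samples_in(design.contrast))
    n_a, n_b = int(ref.sum()), int(con.sum())

    mu_a = values[:, ref].mean(axis=1)
    mu_b = values[:, con].mean(axis=1)
    var_a = values[:, ref].var(axis=1, ddof=1)
    var_b = values[:, con].var(axis=1, ddof=1)

    mu_bar = (mu_a + mu_b) / 2
    var_bar = (var_a + var_b) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu_bar > 0, (var_bar - mu_bar) / mu_bar**2, 0.0)
    alpha = np.clip(alpha, 0.0, None)

    c = PSEUDOCOUNT
    log2fc = np.log2((mu_b + c) / (mu_a + c))
    se = (1 / np.log(2)) * np.sqrt(
        (1 / (mu_a + c) + alpha) / n_a + (1 / (mu_b + c) + alpha) / n_b
    )
    z = np.where(se > 0, log2fc / se, 0.0)
    p = 2 * stats.t.sf(np.abs(z), n_a + n_b - 2)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    # degenerate genes: zero mean and variance in both groups
    dead = (mu_a == 0) & (mu_b == 0) & (var_a == 0) & (var_b == 0)
    log2fc[dead] = 0.0
    z[dead] = 0.0
    p[dead] = 1.0

    table = pd.DataFrame({
        "feature_id": counts.feature_ids,
        "base_mean": (mu_a * n_a + mu_b * n_b) / (n_a + n_b),
        "log2fc": log2fc,
        "se": se,
        "stat": z,
        "p": p,
        "q": _bh_adjust(p),
    })
    return classify_significant(table, TRANSCRIPT)


def log2_normalized_counts(
    counts: ExpressionMatrix, sf: pd.Series, pseudocount: float = PSEUDOCOUNT
) -> ExpressionMatrix:
    """log2(count / size_factor + pseudocount): the variance-tamed
    network input for the transcript layer."""
    values = counts.values() / sf.loc[counts.sample_ids].to_numpy()
    return ExpressionMatrix(
        pd.DataFrame(np.log2(values + pseudocount), index=counts.feature_ids,
                     columns=counts.sample_ids),
        NORMALIZED,
    )


def median_normalize_log2(abundance: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform, then align sample medians.

    Each sample's median (over observed values) is subtracted and the
    global median of sample medians added back, preserving the overall
    scale.  Missing cells stay missing.
    """
    values = abundance.values()
    observed = ~np.isnan(values)
    if (values[observed] <= 0).any():
        raise ValidationError(
            "non-positive abundance; mask as missing before normalizing"
        )
    log2v = np.full_like(values, np.nan)
    np.log2(values, out=log2v, where=observed)
    sample_medians = np.nanmedian(log2v, axis=0)
    normalized = log2v - sample_medians + np.median(sample_medians)
    return ExpressionMatrix(
        pd.DataFrame(normalized, index=abundance.feature_ids,
                     columns=abundance.sample_ids),
        NORMALIZED,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) for residual variances.

    Matches the first two moments of log s^2 under the scaled-F model
    using digamma/trigamma relations.  Returns d0 = inf when the
    observed variances show no excess spread over chi-squared sampling
    noise (then every posterior variance equals s0^2).
    """
    ok = (s2 > 0) & (df > 0)
    s2 = s2[ok]
    df = df[ok]
    if len(s2) < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 1.0
    e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
    e_bar = float(np.mean(e))
    excess = float(np.var(e, ddof=1) * len(e) / (len(e) - 1)
                   - np.mean(special.polygamma(1, df / 2)))
    if excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_bar))
    else:
        d0 = 2 * _trigamma_inverse(excess)
        s0_2 = float(np.exp(e_bar + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_2


def moderated_t_test(
    logabund: ExpressionMatrix, design: SampleDesign, min_per_group: int = 3
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test per protein.

    Complete-case per protein: samples with missing values are dropped
    for that protein; proteins keeping fewer than ``min_per_group``
    observations in either group are excluded (logged).  Residual
    variances are shrunk toward an empirical-Bayes prior fitted across
    proteins; the moderated t is referred to d0 + d_g degrees of
    freedom (standard normal when d0 is infinite).
    """
    values = logabund.values()
    ref = np.isin(logabund.sample_ids, design.samples_in(design.reference))
    con = np.isin(logabund.sample_ids, design.samples_in(design.contrast))

    keep_ids, d_hat, s2, df, n_eff, base = [], [], [], [], [], []
    for i, fid in enumerate(logabund.feature_ids):
        row = values[i]
        obs = ~np.isnan(row)
        a = row[obs & ref]
        b = row[obs & con]
        if len(a) < min_per_group or len(b) < min_per_group:
            logger.info("protein %s excluded: <%d observed per group",
                        fid, min_per_group)
            continue
        na, nb = len(a), len(b)
        pooled = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
            na + nb - 2
        )
        keep_ids.append(fid)
        d_hat.append(float(np.mean(b) - np.mean(a)))
        s2.append(float(pooled))
        df.append(na + nb - 2)
        n_eff.append(1 / na + 1 / nb)
        base.append(float(np.mean(np.concatenate([a, b]))))

    d_hat = np.asarray(d_hat)
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    n_eff = np.asarray(n_eff)

    d0, s0_2 = fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s2_post * n_eff)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, d_hat / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    table = pd.DataFrame({
        "feature_id": keep_ids,
        "base_mean": base,
        "log2fc": d_hat,
        "se": se,
        "stat": t,
        "p": p,
        "q": _bh_adjust(p),
    })
    return classify_significant(table, PROTEIN)


def classify_significant(table: pd.DataFrame, layer: str) -> pd.DataFrame:
    """Apply the layer's significance rule and direction labels.

    Transcripts require p <= 0.05 and |log2FC| >= 0.5; proteins only
    p <= 0.05.  Direction is the sign of log2FC in the subfertile
    (contrast) group.
    """
    table = table.copy()
    if layer == TRANSCRIPT:
        sig = (table["p"] <= P_CUTOFF) & (table["log2fc"].abs() >= LFC_CUTOFF)
    elif layer == PROTEIN:
        sig = table["p"] <= P_CUTOFF
    else:
        raise ValidationError(f"unknown layer {layer!r}")
    table["significant"] = sig
    table["direction"] = np.where(table["log2fc"] >= 0, "up", "down")
    return table


def significant_ids(table: pd.DataFrame) -> list[str]:
    return list(table.loc[table["significant"], "feature_id"])
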