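"""Moderated differential-expression statistics for the two study contrasts.

The study design has one acclimation contrast (engineered ancestor EM vs
wild type WT) and one adaptation contrast per evolved lineage (EVO_l vs EM).
Per-probe statistics use an empirical-Bayes moderated t: probe-wise sample
variances are shrunk toward a common prior variance s0^2 with prior degrees
of freedom d0, both estimated from the distribution of log sample variances
by method of moments (Smyth-style variance squeezing). Probe statistics are
then assimilated to locus level (median effect, Stouffer-combined p) and
adjusted for multiple testing by Benjamini-Hochberg within each contrast.

Effects are oriented as log2(EM/WT) for acclimation and log2(EVO/EM) for
adaptation, so a positive adaptation effect means the evolved strain
increased expression relative to its ancestor.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

ACCLIMATION = "acclimation"
ADAPTATION = "adaptation"


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma is positive on (0, inf)")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-10:
            break
    return float(x)


def squeeze_variances(
    s2: np.ndarray, df: float | np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of genewise variances.

    Fits a scaled inverse-chi-square prior (d0, s0^2) to the observed sample
    variances by method of moments on log s^2, then returns the posterior
    (squeezed) variances ``(d0*s0^2 + df*s2) / (d0 + df)``.

    Returns ``(d0, s0_squared, posterior_variances)``. ``d0`` is ``inf``
    when the log-variances are no more dispersed than sampling alone
    predicts, in which case every posterior variance equals ``s0^2``.
    """
    s2 = np.asarray(s2, dtype=float)
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    positive = s2 > 0
    if not positive.any():
        raise ValueError("all sample variances are zero; prior is undefined")
    z = np.log(s2[positive])
    dfp = df_arr[positive]
    e = z - special.digamma(dfp / 2.0) + np.log(dfp / 2.0)
    e_mean = float(e.mean())
    n = e.size
    if n < 2:
        d0 = math.inf
        s0_sq = float(np.mean(s2))
    else:
        resid = float(np.mean((e - e_mean) ** 2) * n / (n - 1))
        excess = resid - float(np.mean(special.polygamma(1, dfp / 2.0)))
        if excess > 0:
            d0 = 2.0 * trigamma_inverse(excess)
            s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            # log-variances no more dispersed than chi-square sampling alone:
            # every gene shares one variance, best estimated by the plain mean
            d0 = math.inf
            s0_sq = float(np.mean(s2))
    post = _posterior_variance(s2, df_arr, d0, s0_sq)
    return d0, s0_sq, post


def _posterior_variance(
    s2: np.ndarray, df: np.ndarray, d0: float, s0_sq: float
) -> np.ndarray:
    if math.isinf(d0):
        return np.full_like(s2, s0_sq)
    return (d0 * s0_sq + df * s2) / (d0 + df)


def moderated_contrast(
    matrix: ExpressionMatrix,
    baseline: str,
    treatment: str,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-probe moderated t statistics for ``treatment`` vs ``baseline``.

    Parameters
    ----------
    matrix
        Expression matrix with sample sheet.
    baseline, treatment
        Group labels; the effect is mean(treatment) - mean(baseline), i.e.
        log2(treatment/baseline) for log2 intensities.
    prior_df
        Override the estimated prior degrees of freedom d0. ``0`` disables
        moderation (ordinary pooled-variance t); ``inf`` forces every probe
        onto the common prior variance. ``None`` (default) estimates d0.

    Returns
    -------
    DataFrame indexed by probe with columns effect, t, df_resid, df_total,
    p, s2, s2_post.
    """
    a = matrix.group_values(baseline)
    b = matrix.group_values(treatment)
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 replicates")
    effect = b.mean(axis=1) - a.mean(axis=1)
    # pooled within-group variance per probe
    ss = a.sub(a.mean(axis=1), axis=0).pow(2).sum(axis=1) + b.sub(
        b.mean(axis=1), axis=0
    ).pow(2).sum(axis=1)
    df_resid = float(n_a + n_b - 2)
    s2 = (ss / df_resid).to_numpy()
    if prior_df is None:
        d0, s0_sq, s2_post = squeeze_variances(s2, df_resid)
    elif prior_df == 0:
        d0, s0_sq, s2_post = 0.0, float("nan"), s2.copy()
    else:
        d0 = float(prior_df)
        _, s0_sq, _ = squeeze_variances(s2, df_resid)
        s2_post = _posterior_variance(s2, np.full_like(s2, df_resid), d0, s0_sq)
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect.to_numpy() / se
    df_total = d0 + df_resid
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "effect": effect,
            "t": t,
            "df_resid": df_resid,
            "df_total": df_total,
            "p": p,
            "s2": s2,
            "s2_post": s2_post,
        },
        index=a.index,
    )


def assimilate_probes(probe_stats: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Collapse per-probe statistics to one row per locus.

    Locus effect is the median probe effect; the locus p-value combines the
    probes' two-sided p-values with Stouffer's method using the sign of each
    probe's t statistic (so probes with conflicting directions cancel).
    Single-probe loci keep the probe's effect and p exactly.
    """
    unmapped = [p for p in probe_stats.index if p not in probe_map.index]
    if unmapped:
        raise ValueError(f"probes missing from probe map: {unmapped}")
    stats_ = probe_stats.copy()
    stats_["locus"] = probe_map.reindex(stats_.index)

    def _combine(group: pd.DataFrame) -> pd.Series:
        k = len(group)
        effect = float(group["effect"].median())
        p_clip = np.clip(group["p"].to_numpy(), 1e-300, 1.0)
        z = np.sign(group["t"].to_numpy()) * stats.norm.isf(p_clip / 2.0)
        z_comb = float(z.sum() / math.sqrt(k))
        p_comb = float(2.0 * stats.norm.sf(abs(z_comb)))
        if k == 1:
            p_comb = float(group["p"].iloc[0])
        return pd.Series(
            {
                "effect": effect,
                "z": z_comb,
                "p": p_comb,
                "df_total": float(group["df_total"].median()),
                "n_probes": k,
            }
        )

    out = stats_.groupby("locus", sort=True).apply(_combine, include_groups=False)
    out["n_probes"] = out["n_probes"].astype(int)
    return out


def adjust_pvalues(p: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini-Hochberg step-up by default)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def contrast_table(
    matrix: ExpressionMatrix,
    prior_df: float | None = None,
    q_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Full per-locus contrast table for a WT / EM / EVO_* expression matrix.

    Runs the acclimation contrast (EM vs WT) and one adaptation contrast per
    EVO group, assimilates probes to loci, and BH-adjusts p-values within
    each contrast. Returns a tidy frame with columns locus, contrast,
    lineage, effect, z, p, q, n_probes.
    """
    groups = matrix.groups
    if "WT" not in groups or "EM" not in groups:
        raise ValueError("matrix must contain WT and EM groups")
    evo_groups = [g for g in groups if g not in ("WT", "EM")]
    blocks: list[pd.DataFrame] = []

    def _one(baseline: str, treatment: str, label: str, lineage: str) -> pd.DataFrame:
        probe = moderated_contrast(matrix, baseline, treatment, prior_df=prior_df)
        locus = assimilate_probes(probe, matrix.probe_map)
        locus["q"] = adjust_pvalues(locus["p"], method=q_method)
        locus = locus.reset_index()
        locus.insert(1, "contrast", label)
        locus.insert(2, "lineage", lineage)
        return locus

    blocks.append(_one("WT", "EM", ACCLIMATION, ""))
    for group in evo_groups:
        lineage = matrix.samples.loc[matrix.group_columns(group)[0], "lineage"] or group
        blocks.append(_one("EM", group, ADAPTATION, lineage))
    return pd.concat(blocks, ignore_index=True)
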