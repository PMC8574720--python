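"""Moderated two-group differential statistics and per-pipeline MR selection.

Per TR, the HIGH-vs-LOW effect on the activity scale is tested with an
empirical-Bayes moderated t: per-TR pooled variances are shrunk toward a
prior (d0, s0^2) fitted by the method of moments on log variances (trigamma
inversion), the posterior variance is the precision-weighted blend
s~^2 = (d0 s0^2 + d s^2) / (d0 + d), and the t statistic gains d0 prior
degrees of freedom. MEDIUM samples are excluded from differential stages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MraError, PhenotypeLabels

BOOST_GSEA, BOOST_GSVA, BOOST_AREA, MI_AREA = (
    "BOOST_GSEA", "BOOST_GSVA", "BOOST_AREA", "MI_AREA",
)
PIPELINES = (BOOST_GSEA, BOOST_GSVA, BOOST_AREA, MI_AREA)
HIGH_UP, LOW_UP = "HIGH_UP", "LOW_UP"


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on log sample variances."""
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, float(np.median(s2)) if len(s2) else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if not np.isfinite(evar) or evar <= 0:
        return np.nan, np.nan
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t(
    act: pd.DataFrame,
    labels: PhenotypeLabels,
    d0: float | None = None,
) -> pd.DataFrame:
    """Per-TR (effect, moderated t, p) on a TR x sample activity matrix.

    ``d0`` overrides the fitted prior degrees of freedom (0 gives the
    ordinary pooled two-sample t). Returns a DataFrame indexed by TR with
    columns effect, t, p, df, s2, s2_post.
    """
    h = [s for s in labels.high_samples if s in act.columns]
    low = [s for s in labels.low_samples if s in act.columns]
    if len(h) < 2 or len(low) < 2:
        raise MraError("need >= 2 samples per class for differential analysis")
    xh = act[h].to_numpy(dtype=float)
    xl = act[low].to_numpy(dtype=float)
    nh, nl = len(h), len(low)
    effect = xh.mean(axis=1) - xl.mean(axis=1)
    ssh = ((xh - xh.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssl = ((xl - xl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = nh + nl - 2
    s2 = (ssh + ssl) / df

    if d0 is None:
        d0, s0_2 = fit_variance_prior(s2, df)
        if not np.isfinite(d0):
            warnings.warn("variance-prior moment fit failed; falling back to ordinary t")
            d0, s0_2 = 0.0, 0.0
    elif d0 > 0:
        _, s0_2 = fit_variance_prior(s2, df)
        if not np.isfinite(s0_2):
            s0_2 = float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 0.0
    else:
        s0_2 = 0.0
    s2_post = (d0 * s0_2 + df * s2) / (d0 + df) if d0 > 0 else s2.copy()
    se = np.sqrt(s2_post * (1.0 / nh + 1.0 / nl))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    total_df = d0 + df
    p = 2.0 * stats.t.sf(np.abs(t), total_df)
    # degenerate rows: zero variance and zero effect -> no evidence
    degen = (s2_post == 0) & (effect == 0)
    t = np.where(degen, 0.0, t)
    p = np.where(degen, 1.0, p)
    p = np.where(np.isinf(t), 0.0, p)
    return pd.DataFrame(
        {"effect": effect, "t": t, "p": p, "df": total_df, "s2": s2, "s2_post": s2_post},
        index=act.index,
    )


def posterior_variance(s2: float, s0_2: float, d0: float, df: float) -> float:
    """Shrunk variance (d0 s0^2 + df s^2) / (d0 + df)."""
    return (d0 * s0_2 + df * s2) / (d0 + df)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise MraError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gsea_stats(fgsea_df: pd.DataFrame) -> pd.DataFrame:
    """Adapt an fgsea result table to the differential-stats contract."""
    ok = fgsea_df[~fgsea_df["flagged"]].copy()
    out = pd.DataFrame(
        {"effect": ok["nes"], "nes": ok["nes"], "p": ok["p"]}, index=ok.index
    )
    return out


def select_mrs(
    stats_df: pd.DataFrame,
    pipeline: str,
    cohort_id: str = "cohort",
    fdr_threshold: float = 0.05,
    nes_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-pipeline MR selection.

    BOOST_GSEA keeps TRs with FDR <= threshold AND |NES| > nes_threshold;
    the other three pipelines keep all TRs with FDR <= threshold. Returns
    the MR table (effect, t if present, p, fdr, direction, pipeline,
    cohort) for the selected TRs.
    """
    if pipeline not in PIPELINES:
        raise MraError(f"unknown pipeline {pipeline!r}")
    df = stats_df.copy()
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    keep = df["fdr"] <= fdr_threshold
    if pipeline == BOOST_GSEA:
        if "nes" not in df.columns:
            raise MraError("GSEA pipeline selection requires an 'nes' column")
        keep &= df["nes"].abs() > nes_threshold
    out = df.loc[keep].copy()
    out["direction"] = np.where(out["effect"] > 0, HIGH_UP, LOW_UP)
    out["pipeline"] = pipeline
    out["cohort"] = cohort_id
    return out
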