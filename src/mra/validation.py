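"""Projection of MR activity onto held-out cohorts and over-representation
analysis of MR lists.

Projection reuses the discovery regulons: each MR's activity in a held-out
cohort is the mean-difference score over the regulon targets present there.
An MR whose regulon has fewer than ``min_targets`` expressed targets gets
activity 0 and is flagged (the zero convention for genes absent from a
platform). Directional separation between classes is tested with a
one-sided Wilcoxon rank-sum per MR, BH-adjusted within the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import hypergeom, mannwhitneyu

from .activity import _cohort_zscores
from .consensus import HIGH_SPECIFIC, LOW_SPECIFIC
from .differential import bh_adjust
from .grn import SignedRegulon
from .io import ExpressionMatrix, GeneSetCollection, MraError, PhenotypeLabels

logger = logging.getLogger("mra")


@dataclass
class ProjectionReport:
    activities: pd.DataFrame     # MR x held-out samples
    flags: pd.Series             # MR -> True when the zero convention applied
    medians: pd.DataFrame        # MR -> median_high, median_low
    mr_labels: pd.Series         # MR -> HIGH_SPECIFIC / LOW_SPECIFIC
    row_order: list[str]         # clustering order for heatmap display

    def summary(self) -> dict[str, float]:
        """Fraction of MRs whose class medians separate in the labeled
        direction (flagged zero-activity MRs count as failures)."""
        out = {}
        for label, key in ((HIGH_SPECIFIC, "fraction_high_separated"),
                           (LOW_SPECIFIC, "fraction_low_separated")):
            mrs = [m for m in self.medians.index if self.mr_labels[m] == label]
            if not mrs:
                continue
            mh = self.medians.loc[mrs, "median_high"]
            ml = self.medians.loc[mrs, "median_low"]
            good = (mh > ml) if label == HIGH_SPECIFIC else (ml > mh)
            out[key] = float(good.mean())
        return out


def project_activities(
    mr_labels: pd.Series,
    regulons: list[SignedRegulon],
    m_heldout: ExpressionMatrix,
    labels_heldout: PhenotypeLabels,
    min_targets: int = 3,
) -> ProjectionReport:
    """Score discovery MRs on a held-out cohort with the mean-difference engine.

    ``mr_labels`` maps MR id -> HIGH_SPECIFIC / LOW_SPECIFIC. Regulon targets
    absent from the held-out matrix are dropped; below ``min_targets``
    present targets the activity is 0 and the MR is flagged.
    """
    labels_heldout.validate_against(m_heldout)
    if labels_heldout.labels.empty:
        raise MraError("no labeled held-out samples")
    z = _cohort_zscores(m_heldout)
    reg_of = {r.tr_id: r for r in regulons}
    samples = m_heldout.sample_ids
    rows, flags = {}, {}
    for mr in mr_labels.index:
        reg = reg_of.get(mr)
        if reg is None:
            rows[mr] = np.zeros(len(samples))
            flags[mr] = True
            continue
        pos = [t for t in reg.positive_targets if t in z.index]
        neg = [t for t in reg.negative_targets if t in z.index]
        if len(pos) + len(neg) < min_targets:
            rows[mr] = np.zeros(len(samples))
            flags[mr] = True
            continue
        a = z.loc[pos].mean(axis=0).to_numpy() if pos else np.zeros(len(samples))
        b = z.loc[neg].mean(axis=0).to_numpy() if neg else np.zeros(len(samples))
        rows[mr] = a - b
        flags[mr] = False
    act = pd.DataFrame(rows, index=samples).T
    h = labels_heldout.high_samples
    low = labels_heldout.low_samples
    med = pd.DataFrame(
        {
            "median_high": act[h].median(axis=1) if h else np.nan,
            "median_low": act[low].median(axis=1) if low else np.nan,
        }
    )
    order = list(act.index)
    if len(order) > 2:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(act.to_numpy())
        corr = np.nan_to_num(corr, nan=0.0)
        d = 1.0 - corr
        np.fill_diagonal(d, 0.0)
        from scipy.spatial.distance import squareform

        lk = linkage(squareform((d + d.T) / 2.0, checks=False), method="average")
        order = [order[i] for i in leaves_list(lk)]
    return ProjectionReport(act, pd.Series(flags), med, mr_labels.copy(), order)


def activity_significance(
    report: ProjectionReport,
    labels_heldout: PhenotypeLabels,
) -> pd.DataFrame:
    """One-sided rank-sum test per MR in the direction of its label.

    HIGH_SPECIFIC MRs are tested for HIGH > LOW activity and vice versa;
    p-values are BH-adjusted across MRs within the cohort. All-tied
    activities give p = 1.
    """
    h = [s for s in labels_heldout.high_samples if s in report.activities.columns]
    low = [s for s in labels_heldout.low_samples if s in report.activities.columns]
    if len(h) < 2 or len(low) < 2:
        raise MraError("need >= 2 samples per class in the held-out cohort")
    ps = {}
    for mr in report.activities.index:
        x = report.activities.loc[mr, h].to_numpy(dtype=float)
        y = report.activities.loc[mr, low].to_numpy(dtype=float)
        if np.ptp(np.concatenate([x, y])) == 0.0:
            ps[mr] = 1.0
            continue
        alternative = "greater" if report.mr_labels[mr] == HIGH_SPECIFIC else "less"
        ps[mr] = float(mannwhitneyu(x, y, alternative=alternative).pvalue)
    out = pd.DataFrame({"p": pd.Series(ps)})
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def ora_hypergeometric(
    query: list[str],
    sets: GeneSetCollection,
    background: list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a query gene list.

    Sets are intersected with the background before testing;
    p = P(X >= k | N, K, n), BH-adjusted across sets, sorted by FDR. The
    reported ratio is k / K.
    """
    bg = set(background)
    if not bg:
        raise MraError("empty background")
    q = set(query)
    if not q <= bg:
        raise MraError("query must be a subset of the background")
    n = len(q)
    nn = len(bg)
    rows = []
    for name in sorted(sets.sets):
        members = sets[name] & bg
        kk = len(members)
        if kk == 0:
            continue
        overlap = sorted(q & members)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, nn, kk, n))
        rows.append((name, k, kk, n, nn, p, k / kk, ",".join(overlap)))
    out = pd.DataFrame(
        rows, columns=["set", "k", "K", "n", "N", "p", "ratio", "members"]
    )
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["fdr", "p", "set"]).reset_index(drop=True)
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out
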