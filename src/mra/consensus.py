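"""Consensus master-regulator aggregation.

Per cohort, the MRs of the four pipelines are intersected (optionally
requiring a consistent direction). Across cohorts of one prognostic group,
MRs are kept when present (same direction) in all cohorts or in at least a
ceil(fraction * n) share. Each MR is then classified phenotype-specific per
cohort by the quadrant rule on median activities (positive in one class and
negative in the other), and the final HIGH-/LOW-specific lists combine the
group-level votes with a pooled-median filter over all samples of the class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .differential import HIGH_UP, LOW_UP, PIPELINES
from .io import MraError, PhenotypeLabels

logger = logging.getLogger("mra")

HIGH_SPECIFIC, LOW_SPECIFIC, NEITHER = "HIGH_SPECIFIC", "LOW_SPECIFIC", "NEITHER"
ALL, FRACTION = "ALL", "FRACTION"


@dataclass
class CohortGroupDesign:
    """cohort_id -> group (e.g. ENABLED/DISABLED) plus consensus settings."""

    groups: dict[str, str]
    fraction: float = 0.5
    reference_engine: str = "MEANDIFF"

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise MraError("consensus fraction must be in (0, 1]")

    @property
    def group_names(self) -> list[str]:
        return sorted(set(self.groups.values()))

    def cohorts_of(self, group: str) -> list[str]:
        return sorted(c for c, g in self.groups.items() if g == group)


@dataclass
class ConsensusResult:
    per_cohort: dict[str, pd.DataFrame]               # cohort -> (tr, direction)
    evidence: dict[str, pd.DataFrame]                 # group -> (tr, direction, cohorts, n_cohorts)
    medians: pd.DataFrame                             # (tr, cohort, median_high, median_low, defined)
    specificity: pd.DataFrame                         # (tr, cohort, label)
    high_specific: list[str] = field(default_factory=list)
    low_specific: list[str] = field(default_factory=list)


def intersect_pipelines(
    tables: dict[str, pd.DataFrame],
    require_direction_consistency: bool = True,
) -> pd.DataFrame:
    """Intersection of the four pipelines' MR tables for one cohort.

    Returns a DataFrame with columns (tr, direction). A missing pipeline
    table is an error naming the pipeline.
    """
    missing = [p for p in PIPELINES if p not in tables]
    if missing:
        raise MraError(f"missing pipeline table(s): {missing}")
    sets = {p: set(tables[p].index) for p in PIPELINES}
    common = set.intersection(*sets.values())
    rows = []
    for tr in sorted(common):
        dirs = {tables[p].loc[tr, "direction"] for p in PIPELINES}
        if require_direction_consistency and len(dirs) > 1:
            continue
        direction = tables[PIPELINES[0]].loc[tr, "direction"]
        rows.append((tr, direction))
    return pd.DataFrame(rows, columns=["tr", "direction"])


def cross_cancer_consensus(
    per_cohort: dict[str, pd.DataFrame],
    design: CohortGroupDesign,
    mode: str = FRACTION,
) -> dict[str, pd.DataFrame]:
    """Per prognostic group, keep MRs recurring across cohorts.

    ALL: present with the same direction in every cohort of the group.
    FRACTION: present (same direction) in >= ceil(fraction * n) cohorts.
    Evidence cohorts are recorded.
    """
    if mode not in (ALL, FRACTION):
        raise MraError(f"unknown consensus mode {mode!r}")
    out: dict[str, pd.DataFrame] = {}
    for group in design.group_names:
        cohorts = design.cohorts_of(group)
        if not cohorts:
            continue
        need = len(cohorts) if mode == ALL else ceil(design.fraction * len(cohorts))
        votes: dict[tuple[str, str], list[str]] = {}
        for c in cohorts:
            df = per_cohort.get(c)
            if df is None:
                raise MraError(f"missing per-cohort consensus for {c!r}")
            for tr, direction in zip(df["tr"], df["direction"]):
                votes.setdefault((tr, direction), []).append(c)
        rows = [
            (tr, direction, ",".join(cs), len(cs))
            for (tr, direction), cs in sorted(votes.items())
            if len(cs) >= need
        ]
        out[group] = pd.DataFrame(rows, columns=["tr", "direction", "cohorts", "n_cohorts"])
    return out


def classify_specificity(median_high: float, median_low: float) -> str:
    """Quadrant rule: opposite-sign medians decide phenotype specificity."""
    if median_high > 0 and median_low < 0:
        return HIGH_SPECIFIC
    if median_low > 0 and median_high < 0:
        return LOW_SPECIFIC
    return NEITHER


def median_activity_table(
    activities: dict[str, pd.DataFrame],
    labels: dict[str, PhenotypeLabels],
    trs: list[str],
) -> pd.DataFrame:
    """Per MR x cohort median activity in HIGH and LOW samples.

    A TR without a defined activity in a cohort (failed regulon QC there)
    is recorded with medians 0 and defined=False, contributing no
    specificity vote.
    """
    rows = []
    for cohort, act in sorted(activities.items()):
        lab = labels[cohort]
        h = [s for s in lab.high_samples if s in act.columns]
        low = [s for s in lab.low_samples if s in act.columns]
        if not h or not low:
            raise MraError(f"cohort {cohort}: need HIGH and LOW samples with activity")
        for tr in trs:
            if tr in act.index:
                mh = float(act.loc[tr, h].median())
                ml = float(act.loc[tr, low].median())
                rows.append((tr, cohort, mh, ml, True))
            else:
                rows.append((tr, cohort, 0.0, 0.0, False))
    return pd.DataFrame(rows, columns=["tr", "cohort", "median_high", "median_low", "defined"])


def finalize_specific_sets(
    evidence: dict[str, pd.DataFrame],
    medians: pd.DataFrame,
    activities: dict[str, pd.DataFrame],
    labels: dict[str, PhenotypeLabels],
    design: CohortGroupDesign,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Combine group-level specificity votes with the pooled-median filter.

    An MR is group-level HIGH(/LOW)-specific when the quadrant rule labels
    it so in >= ceil(fraction * n_group) cohorts of that group; the final
    HIGH list is the union over groups of such MRs whose pooled median
    activity over all HIGH samples (all cohorts concatenated) is > 0, and
    symmetrically for LOW. An MR qualifying for both lists is dropped with
    a warning. Returns (high_list, low_list, specificity table).
    """
    spec_rows = [
        (r.tr, r.cohort, classify_specificity(r.median_high, r.median_low) if r.defined else NEITHER)
        for r in medians.itertuples()
    ]
    spec = pd.DataFrame(spec_rows, columns=["tr", "cohort", "label"])

    candidates = {HIGH_SPECIFIC: set(), LOW_SPECIFIC: set()}
    for group, ev in evidence.items():
        cohorts = design.cohorts_of(group)
        need = ceil(design.fraction * len(cohorts))
        sub = spec[spec["cohort"].isin(cohorts)]
        for tr in ev["tr"]:
            for label in (HIGH_SPECIFIC, LOW_SPECIFIC):
                n = int(((sub["tr"] == tr) & (sub["label"] == label)).sum())
                if n >= need:
                    candidates[label].add(tr)

    def pooled_median(tr: str, cls: str) -> float:
        vals = []
        for cohort, act in activities.items():
            lab = labels[cohort]
            cols = [s for s in lab.samples_of(cls) if s in act.columns]
            if tr in act.index:
                vals.extend(act.loc[tr, cols].to_numpy(dtype=float))
            else:
                vals.extend([0.0] * len(cols))  # non-TR cohorts score 0
        return float(np.median(vals)) if vals else 0.0

    high = {tr for tr in candidates[HIGH_SPECIFIC] if pooled_median(tr, "HIGH") > 0}
    low = {tr for tr in candidates[LOW_SPECIFIC] if pooled_median(tr, "LOW") > 0}
    conflict = high & low
    if conflict:
        warnings.warn(f"MR(s) in both specific lists dropped: {sorted(conflict)}")
        high -= conflict
        low -= conflict
    return sorted(high), sorted(low), spec


def consensus_analysis(
    mr_tables: dict[str, dict[str, pd.DataFrame]],
    activities: dict[str, pd.DataFrame],
    labels: dict[str, PhenotypeLabels],
    design: CohortGroupDesign,
    mode: str = FRACTION,
    require_direction_consistency: bool = True,
) -> ConsensusResult:
    """Full aggregation: per-cohort intersection, cross-cohort consensus,
    quadrant classification and the final phenotype-specific lists."""
    per_cohort = {
        c: intersect_pipelines(tables, require_direction_consistency)
        for c, tables in mr_tables.items()
    }
    evidence = cross_cancer_consensus(per_cohort, design, mode)
    trs = sorted({tr for ev in evidence.values() for tr in ev["tr"]})
    medians = median_activity_table(activities, labels, trs)
    high, low, spec = finalize_specific_sets(evidence, medians, activities, labels, design)
    return ConsensusResult(per_cohort, evidence, medians, spec, high, low)
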