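"""End-to-end orchestration of the consensus MRA workflow for one or more
cohorts: GRN inference (boosting + MI), regulon signing, the four
scoring/selection pipelines, and the cross-cohort consensus."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import activity as act
from . import differential as diff
from .consensus import CohortGroupDesign, ConsensusResult, consensus_analysis
from .grn import (
    BoostingParams,
    SignedRegulon,
    apply_dpi,
    filter_regulons,
    infer_grn_boosting,
    pairwise_mutual_information,
    sign_regulons,
)
from .io import ExpressionMatrix, PhenotypeLabels

logger = logging.getLogger("mra")


@dataclass
class PipelineConfig:
    min_regulon_size: int = 10
    dpi_tolerance: float = 0.15
    boosting: BoostingParams = field(default_factory=BoostingParams)
    mi_bins: int | None = None
    mi_permutations: int = 200
    mi_alpha: float = 0.05
    gsea_permutations: int = 1000
    gsea_null: str = "gene"        # "gene" (fgsea-style) or "label" (exact under
                                   # group exchangeability, but low-powered for
                                   # co-regulated regulons)
    fdr_threshold: float = 0.05
    nes_threshold: float = 1.0
    seed: int = 0


@dataclass
class CohortRun:
    cohort_id: str
    boost_regulons: list[SignedRegulon]
    mi_regulons: list[SignedRegulon]
    activities: dict[str, pd.DataFrame]   # engine tag -> TR x samples
    mr_tables: dict[str, pd.DataFrame]    # pipeline -> MR table


def build_regulons(
    m: ExpressionMatrix,
    tr_ids: list[str],
    cfg: PipelineConfig,
) -> tuple[list[SignedRegulon], list[SignedRegulon]]:
    """Infer, filter and sign the boosting and MI regulons for one cohort."""
    bp = cfg.boosting
    bp = BoostingParams(**{**bp.__dict__, "seed": cfg.seed})
    boost_net = infer_grn_boosting(m, tr_ids, bp)
    boost_net = filter_regulons(boost_net, cfg.min_regulon_size)
    boost_reg = sign_regulons(boost_net, m, cfg.min_regulon_size)

    mi_net = pairwise_mutual_information(
        m, tr_ids, n_bins=cfg.mi_bins, n_perm=cfg.mi_permutations,
        alpha=cfg.mi_alpha, seed=cfg.seed,
    )
    mi_net = apply_dpi(mi_net, cfg.dpi_tolerance)
    mi_net = filter_regulons(mi_net, cfg.min_regulon_size)
    mi_reg = sign_regulons(mi_net, m, cfg.min_regulon_size)
    return boost_reg, mi_reg


def run_cohort(
    m: ExpressionMatrix,
    labels: PhenotypeLabels,
    tr_ids: list[str],
    cfg: PipelineConfig | None = None,
    regulons: tuple[list[SignedRegulon], list[SignedRegulon]] | None = None,
) -> CohortRun:
    """Run the four MRA pipelines on one cohort.

    ``regulons`` can inject pre-built (boosting, MI) regulons to skip
    network inference.
    """
    cfg = cfg or PipelineConfig()
    labels.validate_against(m)
    labels.require_two_classes()
    if regulons is None:
        boost_reg, mi_reg = build_regulons(m, tr_ids, cfg)
    else:
        boost_reg, mi_reg = regulons

    activities = {
        "MEANDIFF": act.meandiff_matrix(m, boost_reg),
        "AREA_BOOST": act.area_matrix(m, boost_reg),
        "AREA_MI": act.area_matrix(m, mi_reg),
        "GSVA": act.gsva_scores(m, boost_reg),
    }

    if cfg.gsea_null == "label":
        gsea = act.fgsea_label_scores(
            m, labels, boost_reg, n_perm=cfg.gsea_permutations, seed=cfg.seed
        )
    else:
        fc = act.fold_change_signature(m, labels)
        gsea = act.fgsea_scores(fc, boost_reg, n_perm=cfg.gsea_permutations, seed=cfg.seed)

    mr_tables = {}
    sel = dict(fdr_threshold=cfg.fdr_threshold, nes_threshold=cfg.nes_threshold)
    mr_tables[diff.BOOST_GSEA] = diff.select_mrs(
        diff.gsea_stats(gsea), diff.BOOST_GSEA, labels.cohort_id, **sel
    )
    mr_tables[diff.BOOST_GSVA] = diff.select_mrs(
        diff.moderated_t(activities["GSVA"], labels), diff.BOOST_GSVA, labels.cohort_id, **sel
    )
    mr_tables[diff.BOOST_AREA] = diff.select_mrs(
        diff.moderated_t(activities["AREA_BOOST"], labels), diff.BOOST_AREA, labels.cohort_id, **sel
    )
    mr_tables[diff.MI_AREA] = diff.select_mrs(
        diff.moderated_t(activities["AREA_MI"], labels), diff.MI_AREA, labels.cohort_id, **sel
    )
    return CohortRun(labels.cohort_id, boost_reg, mi_reg, activities, mr_tables)


def run_study(
    runs: dict[str, CohortRun],
    labels: dict[str, PhenotypeLabels],
    design: CohortGroupDesign,
    mode: str = "FRACTION",
) -> ConsensusResult:
    """Aggregate per-cohort runs into the consensus MR sets."""
    mr_tables = {c: r.mr_tables for c, r in runs.items()}
    activities = {c: r.activities[design.reference_engine] for c, r in runs.items()}
    return consensus_analysis(mr_tables, activities, labels, design, mode)
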