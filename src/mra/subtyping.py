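"""Phenotype labeling by consensus clustering on an immune-activation signature.

Samples are partitioned into three classes (HIGH / MEDIUM / LOW immune
activation) by repeated subsampled Ward hierarchical clustering over the
z-scored signature genes; the final partition comes from clustering the
consensus (co-clustering frequency) matrix, and clusters are ordered by mean
signature expression to assign the class labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import HIGH, LOW, MEDIUM, ExpressionMatrix, MraError, PhenotypeLabels

logger = logging.getLogger("mra")

# 20-gene immune-activation ("immunologic constant of rejection") signature:
# CXCR3/CCR5 chemokines, Th1/IFN-gamma signaling, cytotoxic effectors and
# immune-regulatory checkpoints.
ICR_SIGNATURE: list[str] = [
    "CXCL9", "CXCL10", "CCL5",
    "IFNG", "IL12B", "TBX21", "CD8A", "CD8B", "STAT1", "IRF1",
    "GNLY", "PRF1", "GZMA", "GZMB", "GZMH",
    "CD274", "CTLA4", "FOXP3", "IDO1", "PDCD1",
]


@dataclass
class SignatureDefinition:
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise MraError("empty signature")
        if len(set(self.genes)) != len(self.genes):
            raise MraError("duplicate genes in signature")


DEFAULT_SIGNATURE = SignatureDefinition(list(ICR_SIGNATURE))


@dataclass
class ConsensusMatrix:
    """Samples x samples co-clustering frequencies in [0,1], unit diagonal."""

    matrix: pd.DataFrame
    b: int

    def __post_init__(self) -> None:
        v = self.matrix.to_numpy()
        if not np.allclose(v, v.T):
            raise MraError("consensus matrix must be symmetric")
        if (v < 0).any() or (v > 1).any():
            raise MraError("consensus entries must lie in [0,1]")


def _signature_zscores(m: ExpressionMatrix, sig: SignatureDefinition) -> pd.DataFrame:
    present = [g for g in sig.genes if g in m.data.index]
    if not present:
        missing = [g for g in sig.genes if g not in m.data.index]
        raise MraError(f"no signature genes present; missing: {missing}")
    if len(present) < 2:
        raise MraError("need >= 2 signature genes present")
    sub = m.data.loc[present]
    sd = sub.std(axis=1, ddof=0).replace(0.0, np.nan)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0).fillna(0.0)
    return z  # genes x samples


def consensus_cluster(
    m: ExpressionMatrix,
    sig: SignatureDefinition = DEFAULT_SIGNATURE,
    k: int = 3,
    b: int = 100,
    subsample: float = 0.8,
    seed: int = 0,
) -> ConsensusMatrix:
    """Co-clustering frequencies over B sample subsamples.

    Each resample (without replacement) is clustered by Ward-linkage
    hierarchical clustering on Euclidean distance over the z-scored
    signature genes and cut at k. consensus(i,j) = co-cluster count /
    co-sample count; never co-sampled pairs get 0.
    """
    z = _signature_zscores(m, sig)
    z = z[sorted(z.columns)]  # canonical sample order: labels are order-invariant
    n = z.shape[1]
    if n < 3 * k:
        raise MraError(f"need at least {3 * k} samples for k={k}")
    x = z.to_numpy().T  # samples x genes
    rng = np.random.default_rng(seed)
    size = max(k, int(round(subsample * n)))
    co = np.zeros((n, n))
    tog = np.zeros((n, n))
    for _ in range(b):
        idx = np.sort(rng.choice(n, size=size, replace=False))
        lab = fcluster(linkage(x[idx], method="ward"), k, criterion="maxclust")
        tog[np.ix_(idx, idx)] += 1
        same = lab[:, None] == lab[None, :]
        co[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore"):
        cons = np.where(tog > 0, co / np.maximum(tog, 1), 0.0)
    never = int(((tog == 0).sum() - (np.diag(tog) == 0).sum()) // 2)
    if never:
        logger.warning("%d sample pairs never co-sampled; consensus set to 0", never)
    np.fill_diagonal(cons, 1.0)
    ids = list(z.columns)
    return ConsensusMatrix(pd.DataFrame(cons, index=ids, columns=ids), b)


def label_icr_classes(
    cm: ConsensusMatrix,
    m: ExpressionMatrix,
    sig: SignatureDefinition = DEFAULT_SIGNATURE,
    k: int = 3,
    cohort_id: str = "cohort",
    cohort_group: str = "UNSPECIFIED",
) -> PhenotypeLabels:
    """Cut the consensus dissimilarity at k and order clusters by mean
    signature expression: top cluster -> HIGH, bottom -> LOW, rest MEDIUM."""
    ids = list(cm.matrix.index)
    d = 1.0 - cm.matrix.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    lab = fcluster(linkage(squareform(d, checks=False), method="ward"), k, criterion="maxclust")
    z = _signature_zscores(m, sig)[ids]
    means = {}
    sizes = {}
    for c in np.unique(lab):
        members = lab == c
        means[c] = float(z.to_numpy()[:, members].mean())
        sizes[c] = int(members.sum())
    ties = len(set(means.values())) < len(means)
    if ties:
        warnings.warn("tie in cluster mean signature expression; larger cluster ranked first")
    # descending mean, ties broken by larger cluster first
    order = sorted(means, key=lambda c: (-means[c], -sizes[c], c))
    class_of = {order[0]: HIGH, order[-1]: LOW}
    for c in order[1:-1]:
        class_of[c] = MEDIUM
    labels = pd.Series([class_of[c] for c in lab], index=ids)
    return PhenotypeLabels(labels, cohort_id=cohort_id, cohort_group=cohort_group)


def subtype_cohort(
    m: ExpressionMatrix,
    sig: SignatureDefinition = DEFAULT_SIGNATURE,
    k: int = 3,
    b: int = 100,
    subsample: float = 0.8,
    seed: int = 0,
    cohort_id: str = "cohort",
    cohort_group: str = "UNSPECIFIED",
) -> tuple[PhenotypeLabels, ConsensusMatrix]:
    cm = consensus_cluster(m, sig, k=k, b=b, subsample=subsample, seed=seed)
    return label_icr_classes(cm, m, sig, k=k, cohort_id=cohort_id, cohort_group=cohort_group), cm
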