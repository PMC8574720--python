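"""Regulon activity scoring engines on a common TR x sample scale.

Four engines estimate how active a regulator's program is:

* MEANDIFF — difference in average single-sample z-score between the
  positively and negatively regulated targets;
* AREA — analytic rank-based enrichment: a weighted mode-signed average of
  normal-quantile-mapped target scores, standard normal under the null, so a
  two-sided p follows in closed form;
* GSVA — single-sample enrichment from a kernel-CDF rank statistic and a
  signed weighted Kolmogorov-Smirnov random walk;
* GSEA — two-group weighted-KS enrichment of the regulon in the fold-change
  signature, with a gene-permutation null giving NES and p.

Ranking ties are broken by stable gene-id order throughout so results are
machine-independent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .grn import SignedRegulon
from .io import ExpressionMatrix, MraError, PhenotypeLabels

logger = logging.getLogger("mra")

MEANDIFF, AREA, GSVA, GSEA = "MEANDIFF", "AREA", "GSVA", "GSEA"
SINGLE_SAMPLE_Z, FOLD_CHANGE = "SINGLE_SAMPLE_Z", "FOLD_CHANGE"


@dataclass
class SignatureVector:
    """Per-gene real scores (a pandas Series indexed by gene id)."""

    values: pd.Series
    kind: str = SINGLE_SAMPLE_Z

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise MraError("duplicate genes in signature vector")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise MraError("non-finite signature values")


def _cohort_zscores(m: ExpressionMatrix) -> pd.DataFrame:
    """Row z-scores across the cohort; zero-sd genes dropped."""
    if m.n_samples < 3:
        raise MraError("need >= 3 samples to define the cohort signature")
    x = m.data
    sd = x.std(axis=1, ddof=0)
    keep = sd > 0
    x = x.loc[keep]
    return x.sub(x.mean(axis=1), axis=0).div(sd[keep], axis=0)


def single_sample_signature(m: ExpressionMatrix, sample: str) -> SignatureVector:
    """Cohort z-score of one sample's expression (constant genes excluded)."""
    z = _cohort_zscores(m)
    return SignatureVector(z[sample], SINGLE_SAMPLE_Z)


def rank_to_normal(sig: SignatureVector) -> SignatureVector:
    """Map scores to normal quantiles Phi^-1(rank / (G + 1)).

    Ties are broken by stable gene-id order so the mapping is deterministic.
    """
    s = sig.values
    ids = np.asarray(s.index, dtype=object)
    id_rank = np.argsort(np.argsort(ids, kind="stable"))
    order = np.lexsort((id_rank, s.to_numpy()))
    g = len(s)
    q = np.empty(g)
    q[order] = norm.ppf((np.arange(1, g + 1)) / (g + 1))
    return SignatureVector(pd.Series(q, index=s.index), sig.kind)


def meandiff_activity(reg: SignedRegulon, sig: SignatureVector) -> float:
    """mean(z over positive targets) - mean(z over negative targets).

    An empty mode-group contributes 0; no targets present at all is an error
    (the caller flags and excludes the TR for that cohort).
    """
    s = sig.values
    pos = [t for t in reg.positive_targets if t in s.index]
    neg = [t for t in reg.negative_targets if t in s.index]
    if not pos and not neg:
        raise MraError(f"no regulon targets of {reg.tr_id} present in signature")
    a = float(s.loc[pos].mean()) if pos else 0.0
    b = float(s.loc[neg].mean()) if neg else 0.0
    return a - b


def area_nes(reg: SignedRegulon, sig_mapped: SignatureVector) -> float:
    """Analytic NES: sum_i w_i m_i q_i / sqrt(sum w_i^2).

    ``sig_mapped`` must hold normal-quantile-mapped scores; under an
    independent standard-normal null the statistic is standard normal, so
    p = 2 * Phi(-|NES|).
    """
    s = sig_mapped.values
    present = [i for i, t in enumerate(reg.targets) if t in s.index]
    if not present:
        raise MraError(f"no regulon targets of {reg.tr_id} present in signature")
    w = reg.confidence[present]
    mmode = reg.modes[present]
    q = s.loc[[reg.targets[i] for i in present]].to_numpy()
    return float((w * mmode * q).sum() / np.sqrt((w**2).sum()))


def area_p(nes: float) -> float:
    return float(2.0 * norm.cdf(-abs(nes)))


def meandiff_matrix(m: ExpressionMatrix, regulons: list[SignedRegulon]) -> pd.DataFrame:
    """TR x sample MEANDIFF activity matrix (vectorized over samples)."""
    z = _cohort_zscores(m)
    rows, index = [], []
    for reg in regulons:
        pos = [t for t in reg.positive_targets if t in z.index]
        neg = [t for t in reg.negative_targets if t in z.index]
        if not pos and not neg:
            logger.warning("TR %s has no present targets; excluded", reg.tr_id)
            continue
        a = z.loc[pos].mean(axis=0) if pos else 0.0
        b = z.loc[neg].mean(axis=0) if neg else 0.0
        rows.append(a - b)
        index.append(reg.tr_id)
    return pd.DataFrame(rows, index=index, columns=m.sample_ids, dtype=float)


def area_matrix(m: ExpressionMatrix, regulons: list[SignedRegulon]) -> pd.DataFrame:
    """TR x sample analytic-NES activity matrix."""
    z = _cohort_zscores(m)
    genes = list(z.index)
    g = len(genes)
    # per-sample rank -> normal quantile, ties broken by gene id
    zv = z.to_numpy()
    id_rank = np.argsort(np.argsort(np.asarray(genes, dtype=object), kind="stable"))
    q = np.empty_like(zv)
    quantiles = norm.ppf(np.arange(1, g + 1) / (g + 1))
    for j in range(zv.shape[1]):
        order = np.lexsort((id_rank, zv[:, j]))
        q[order, j] = quantiles
    qdf = pd.DataFrame(q, index=genes, columns=z.columns)
    rows, names = [], []
    for reg in regulons:
        present = [i for i, t in enumerate(reg.targets) if t in qdf.index]
        if not present:
            logger.warning("TR %s has no present targets; excluded", reg.tr_id)
            continue
        w = reg.confidence[present]
        mmode = reg.modes[present]
        qs = qdf.loc[[reg.targets[i] for i in present]].to_numpy()
        rows.append((w * mmode) @ qs / np.sqrt((w**2).sum()))
        names.append(reg.tr_id)
    return pd.DataFrame(rows, index=names, columns=m.sample_ids, dtype=float)


# ---------------------------------------------------------------------------
# GSVA-style single-sample scores


def _kernel_cdf_scores(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene Gaussian-kernel CDF of each sample's value across the cohort."""
    x = m.data.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    h = np.maximum(sd / 4.0, 1e-6)
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        out[i] = norm.cdf((x[i][:, None] - x[i][None, :]) / h[i]).mean(axis=1)
    return pd.DataFrame(out, index=m.data.index, columns=m.data.columns)


def gsva_set_score(f_ranked_r: np.ndarray, hit_mask: np.ndarray, tau: float = 1.0) -> float:
    """Exact O(G) walk for one set (reference implementation)."""
    g = len(f_ranked_r)
    k = int(hit_mask.sum())
    if k == 0:
        return 0.0
    r = f_ranked_r**tau
    wsum = r[hit_mask].sum()
    if k == g or wsum == 0:
        return 1.0 if wsum > 0 else 0.0
    steps = np.where(hit_mask, r / wsum, -1.0 / (g - k))
    walk = np.cumsum(steps)
    return float(max(walk.max(), 0.0) + min(walk.min(), 0.0))


def gsva_scores(
    m: ExpressionMatrix,
    regulons: list[SignedRegulon],
    tau: float = 1.0,
) -> pd.DataFrame:
    """TR x sample GSVA-style activity matrix.

    Per sample, genes are ranked by decreasing kernel-CDF score F (ties by
    gene id), the rank statistic is r_g = |G/2 - rank_g|, and each mode-set
    is scored by a weighted KS walk with the signed-sum statistic; the
    regulon score is score(positive set) - score(negative set).
    """
    if m.n_samples < 4:
        raise MraError("need >= 4 samples for GSVA scoring")
    f = _kernel_cdf_scores(m)
    genes = np.asarray(f.index, dtype=object)
    g = len(genes)
    gene_rank_key = np.argsort(np.argsort(genes, kind="stable"))
    fv = f.to_numpy()
    ranks_all = np.empty((g, m.n_samples), dtype=int)
    for j in range(m.n_samples):
        order = np.lexsort((gene_rank_key, -fv[:, j]))
        ranks_all[order, j] = np.arange(1, g + 1)
    r_stat = np.abs(g / 2.0 - ranks_all) ** tau  # genes x samples

    idx_of = {t: i for i, t in enumerate(genes)}
    rows, names = [], []
    for reg in regulons:
        pos = np.array([idx_of[t] for t in reg.positive_targets if t in idx_of], dtype=int)
        neg = np.array([idx_of[t] for t in reg.negative_targets if t in idx_of], dtype=int)
        if pos.size == 0 and neg.size == 0:
            logger.warning("TR %s has no present targets; excluded", reg.tr_id)
            continue
        scores = np.zeros(m.n_samples)
        for j in range(m.n_samples):
            sp = _set_walk(r_stat[:, j], ranks_all[:, j], pos, g) if pos.size else 0.0
            sn = _set_walk(r_stat[:, j], ranks_all[:, j], neg, g) if neg.size else 0.0
            scores[j] = sp - sn
        rows.append(scores)
        names.append(reg.tr_id)
    return pd.DataFrame(rows, index=names, columns=m.sample_ids, dtype=float)


def _set_walk(r_stat_col: np.ndarray, ranks_col: np.ndarray, set_idx: np.ndarray, g: int) -> float:
    k = set_idx.size
    hit_pos = np.sort(ranks_col[set_idx] - 1)
    r_hit = r_stat_col[set_idx][np.argsort(ranks_col[set_idx], kind="stable")]
    wsum = r_hit.sum()
    if k == g:
        return 1.0 if wsum > 0 else 0.0
    if wsum == 0:
        return 0.0
    cum = np.cumsum(r_hit) / wsum
    miss = 1.0 / (g - k)
    j = np.arange(k)
    dev_after = cum - (hit_pos - j) * miss
    dev_before = np.concatenate(([0.0], cum[:-1])) - (hit_pos - j) * miss
    # between hits the walk decreases, so extremes occur just after a hit or
    # just before the next one; the walk ends at 0, covered by the 0 bounds
    max_pos = max(0.0, float(dev_after.max()), float(dev_before.max()))
    min_neg = min(0.0, float(dev_after.min()), float(dev_before.min()))
    return max_pos + min_neg


# ---------------------------------------------------------------------------
# two-group GSEA


def fold_change_signature(m: ExpressionMatrix, labels: PhenotypeLabels) -> SignatureVector:
    """Per-gene mean(HIGH) - mean(LOW) expression difference."""
    labels.validate_against(m)
    labels.require_two_classes()
    h = m.data[labels.high_samples].mean(axis=1)
    low = m.data[labels.low_samples].mean(axis=1)
    return SignatureVector(h - low, FOLD_CHANGE)


def _ranked(sig: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Genes sorted by decreasing score, ties by gene id; returns
    (sorted values, sorted gene array)."""
    genes = np.asarray(sig.index, dtype=object)
    key = np.argsort(np.argsort(genes, kind="stable"))
    order = np.lexsort((key, -sig.to_numpy()))
    return sig.to_numpy()[order], genes[order]


def gsea_es(sig: SignatureVector, gene_set, exponent: float = 1.0) -> float:
    """Weighted-KS enrichment score by explicit running sum.

    Hit steps add |s|^p / sum_hits |s|^p, miss steps subtract 1/(G - k);
    the ES is the deviation of maximum absolute value (signed).
    """
    vals, genes = _ranked(sig.values)
    in_set = np.isin(genes, list(gene_set))
    k = int(in_set.sum())
    if k == 0:
        raise MraError("no set gene present in signature")
    g = len(genes)
    wsum = np.abs(vals[in_set]) ** exponent
    total = wsum.sum()
    if total == 0:
        return 0.0
    if k == g:
        return 1.0
    # cumulate hit weights before normalizing so exact ties are stable
    hit_cum = np.cumsum(np.where(in_set, np.abs(vals) ** exponent, 0.0)) / total
    miss_cum = np.cumsum(~in_set) / (g - k)
    walk = hit_cum - miss_cum
    mx, mn = float(walk.max()), float(walk.min())
    return mx if mx >= -mn else mn


def _es_from_positions(absw_sorted: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Vectorized ES for many same-size sets given 0-based sorted positions.

    ``absw_sorted``: |s|^p in ranked order; ``positions``: (n_sets, k) each
    row sorted ascending. Matches gsea_es exactly (walk extremes occur just
    after a hit or just before the next hit).
    """
    n_sets, k = positions.shape
    g = len(absw_sorted)
    hitw = absw_sorted[positions]
    totals = hitw.sum(axis=1, keepdims=True)
    miss = 1.0 / (g - k)
    j = np.arange(k)[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        cum = np.cumsum(hitw, axis=1) / totals
    pre = (positions - j) * miss
    dev_after = cum - pre
    dev_before = np.concatenate([np.zeros((n_sets, 1)), cum[:, :-1]], axis=1) - pre
    mx = np.maximum(dev_after.max(axis=1), np.maximum(dev_before.max(axis=1), 0.0))
    mn = np.minimum(dev_after.min(axis=1), np.minimum(dev_before.min(axis=1), 0.0))
    es = np.where(mx >= -mn, mx, mn)
    es = np.where(np.ravel(totals) == 0, 0.0, es)
    return es


def fgsea_scores(
    sig: SignatureVector,
    regulons: list[SignedRegulon],
    n_perm: int = 1000,
    seed: int = 0,
    exponent: float = 1.0,
) -> pd.DataFrame:
    """Permutation GSEA of signed regulons against a fold-change signature.

    Per regulon the signature is mode-adjusted (targets multiplied by their
    mode), the ES of the target set is computed, and a gene-permutation null
    of ``n_perm`` random same-size sets yields
    NES = ES / mean(|ES_null| of the same sign) and
    p = (1 + #{same-sign |ES_null| >= |ES|}) / (1 + #same-sign nulls).
    """
    if sig.kind != FOLD_CHANGE:
        warnings.warn("fgsea_scores expects a fold-change signature")
    rng = np.random.default_rng(seed)
    rows = []
    for reg in regulons:
        s = sig.values.copy()
        present = [t for t in reg.targets if t in s.index]
        if not present:
            rows.append((reg.tr_id, np.nan, np.nan, np.nan, 0, True))
            continue
        mode_of = dict(zip(reg.targets, reg.modes))
        s.loc[present] = s.loc[present] * np.array([mode_of[t] for t in present])
        es = gsea_es(SignatureVector(s, sig.kind), present, exponent)
        vals, genes = _ranked(s)
        absw = np.abs(vals) ** exponent
        g = len(genes)
        k = len(present)
        if k >= g:
            rows.append((reg.tr_id, es, np.nan, 1.0, 0, True))
            continue
        pos = np.argsort(rng.random((n_perm, g)), axis=1)[:, :k]
        pos.sort(axis=1)
        es_null = _es_from_positions(absw, pos)
        same = es_null * es > 0 if es != 0 else es_null == 0
        n_same = int(same.sum())
        if n_same == 0:
            rows.append((reg.tr_id, es, np.nan, 1.0, n_perm, True))
            continue
        nes = es / np.abs(es_null[same]).mean()
        p = (1 + int((np.abs(es_null[same]) >= abs(es)).sum())) / (1 + n_same)
        rows.append((reg.tr_id, es, nes, p, n_perm, False))
    return pd.DataFrame(
        rows, columns=["tr", "es", "nes", "p", "n_perm", "flagged"]
    ).set_index("tr")


def _es_per_column(adj: np.ndarray, target_idx: np.ndarray) -> np.ndarray:
    """ES of one target set in every column of a signature matrix.

    ``adj``: genes x columns mode-adjusted signature values; ``target_idx``:
    row indices of the set. Vectorized over columns via the position form of
    the weighted-KS walk.
    """
    g, ncol = adj.shape
    k = len(target_idx)
    order = np.argsort(-adj, axis=0, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(g)[:, None], axis=0)
    pos = ranks[target_idx, :]                       # k x ncol
    w = np.abs(adj[target_idx, :])
    sort_idx = np.argsort(pos, axis=0)
    pos_s = np.take_along_axis(pos, sort_idx, axis=0)
    w_s = np.take_along_axis(w, sort_idx, axis=0)
    totals = w_s.sum(axis=0)
    miss = 1.0 / (g - k)
    j = np.arange(k)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        cum = np.cumsum(w_s, axis=0) / totals
    pre = (pos_s - j) * miss
    dev_after = cum - pre
    dev_before = np.vstack([np.zeros(ncol), cum[:-1]]) - pre
    mx = np.maximum(dev_after.max(axis=0), np.maximum(dev_before.max(axis=0), 0.0))
    mn = np.minimum(dev_after.min(axis=0), np.minimum(dev_before.min(axis=0), 0.0))
    es = np.where(mx >= -mn, mx, mn)
    return np.where(totals == 0, 0.0, es)


def fgsea_label_scores(
    m: ExpressionMatrix,
    labels: PhenotypeLabels,
    regulons: list[SignedRegulon],
    n_perm: int = 1000,
    seed: int = 0,
    exponent: float = 1.0,
) -> pd.DataFrame:
    """Regulon GSEA with a phenotype-label permutation null.

    The observed ES is computed exactly as in :func:`fgsea_scores` on the
    HIGH-vs-LOW fold-change signature. The null re-draws the group
    assignment: each permutation shuffles the class labels across the
    labeled samples and recomputes the fold-change signature, so the null
    preserves the gene-gene correlation of the cohort (co-regulated regulon
    targets do not inflate the enrichment). Exact under exchangeability of
    the two classes; gene-permutation is available via ``fgsea_scores``.
    """
    labels.validate_against(m)
    labels.require_two_classes()
    h, low = labels.high_samples, labels.low_samples
    cols = h + low
    x = m.data[cols].to_numpy(dtype=float)
    nh = len(h)
    n = len(cols)
    rng = np.random.default_rng(seed)
    # contrast matrix: column p holds +1/nh on permuted HIGH, -1/nl elsewhere
    contrasts = np.empty((n, n_perm))
    base = np.concatenate([np.full(nh, 1.0 / nh), np.full(n - nh, -1.0 / (n - nh))])
    for p in range(n_perm):
        contrasts[:, p] = base[rng.permutation(n)]
    fc_null = x @ contrasts                     # genes x n_perm
    fc_obs = fold_change_signature(m, labels)

    genes = list(m.data.index)
    idx_of = {gid: i for i, gid in enumerate(genes)}
    rows = []
    for reg in regulons:
        present = [t for t in reg.targets if t in idx_of]
        if not present:
            rows.append((reg.tr_id, np.nan, np.nan, np.nan, 0, True))
            continue
        mode_of = dict(zip(reg.targets, reg.modes))
        s = fc_obs.values.copy()
        s.loc[present] = s.loc[present] * np.array([mode_of[t] for t in present])
        es = gsea_es(SignatureVector(s, FOLD_CHANGE), present, exponent)
        target_idx = np.array([idx_of[t] for t in present])
        adj = fc_null * 1.0
        adj[target_idx, :] *= np.array([mode_of[t] for t in present])[:, None]
        if exponent != 1.0:
            adj = np.sign(adj) * np.abs(adj) ** exponent
        es_null = _es_per_column(adj, target_idx)
        same = es_null * es > 0 if es != 0 else es_null == 0
        n_same = int(same.sum())
        if n_same == 0:
            rows.append((reg.tr_id, es, np.nan, 1.0, n_perm, True))
            continue
        nes = es / np.abs(es_null[same]).mean()
        p = (1 + int((np.abs(es_null[same]) >= abs(es)).sum())) / (1 + n_same)
        rows.append((reg.tr_id, es, nes, p, n_perm, False))
    return pd.DataFrame(
        rows, columns=["tr", "es", "nes", "p", "n_perm", "flagged"]
    ).set_index("tr")


def activity_matrix(
    m: ExpressionMatrix,
    regulons: list[SignedRegulon],
    engine: str = MEANDIFF,
) -> pd.DataFrame:
    """Dispatch to the per-sample engines (MEANDIFF, AREA, GSVA)."""
    if engine == MEANDIFF:
        return meandiff_matrix(m, regulons)
    if engine == AREA:
        return area_matrix(m, regulons)
    if engine == GSVA:
        return gsva_scores(m, regulons)
    raise MraError(f"unknown per-sample engine {engine!r}")
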