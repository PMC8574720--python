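"""Gene regulatory network inference and regulon construction.

Two engines reverse-engineer weighted TR -> target networks from expression:

* a regularized gradient-boosting engine: per target gene, a boosted ensemble
  of shallow regression trees predicts the target's (z-scored) row from the
  candidate-regulator rows; the importance of a regulator is the total
  squared-error reduction (gain) attributed to splits on it, and a
  permuted-target null run filters out importances attributable to noise;
* a mutual-information engine: equal-frequency binning, Miller-Madow
  corrected plug-in MI, a permutation keep-threshold, and data-processing
  inequality (DPI) pruning of presumptively indirect edges.

Regulons below the minimum size are dropped, and retained regulons are
signed by the Spearman correlation between regulator and target rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, MraError

logger = logging.getLogger("mra")

BOOSTING, MI = "BOOSTING", "MI"


@dataclass
class WeightedNetwork:
    """Edge table (regulator, target, weight > 0) with an engine tag."""

    edges: pd.DataFrame
    engine: str

    def __post_init__(self) -> None:
        e = self.edges
        required = {"regulator", "target", "weight"}
        if not required.issubset(e.columns):
            raise MraError(f"edge table needs columns {sorted(required)}")
        if len(e):
            w = e["weight"].to_numpy(dtype=float)
            if not np.isfinite(w).all() or (w <= 0).any():
                raise MraError("edge weights must be finite and > 0")
            if (e["regulator"] == e["target"]).any():
                raise MraError("self-loop in network")

    def regulon_sizes(self) -> pd.Series:
        return self.edges.groupby("regulator").size()

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class SignedRegulon:
    """One TR's targets with per-target mode (+/-1) and confidence in (0,1]."""

    tr_id: str
    targets: list[str]
    modes: np.ndarray
    confidence: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.targets)) != len(self.targets):
            raise MraError(f"duplicate targets in regulon {self.tr_id}")
        if not np.isin(self.modes, (-1, 1)).all():
            raise MraError("modes must be -1 or +1")

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def positive_targets(self) -> list[str]:
        return [t for t, m in zip(self.targets, self.modes) if m == 1]

    @property
    def negative_targets(self) -> list[str]:
        return [t for t, m in zip(self.targets, self.modes) if m == -1]

    def flipped(self) -> "SignedRegulon":
        return SignedRegulon(self.tr_id, list(self.targets), -self.modes, self.confidence.copy())


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


@dataclass
class BoostingParams:
    n_rounds: int = 300
    learning_rate: float = 0.05
    max_depth: int = 2
    row_subsample: float = 0.9
    regulator_subsample: float = 0.3
    theta: float = 0.33          # keep edges with rescaled importance >= theta
    top_k: int = 25              # cap regulators per target
    null_margin: float = 2.0     # edges must beat null_margin * permuted-run max gain
    seed: int = 0


def infer_grn_boosting(
    m: ExpressionMatrix,
    tr_ids: list[str],
    params: BoostingParams | None = None,
) -> WeightedNetwork:
    """Boosted-tree importance network over all target genes.

    Per-target edge retention: gain importances are compared against the
    maximum importance obtained on a target-permuted copy (null filter),
    rescaled to max 1, thresholded at ``theta`` and capped at ``top_k``
    regulators. Zero-variance targets are skipped with a warning.
    """
    params = params or BoostingParams()
    tr_ids = sorted(set(tr_ids))
    missing = set(tr_ids) - set(m.gene_ids)
    if missing:
        raise MraError(f"TRs absent from matrix: {sorted(missing)[:5]}")
    if m.n_samples < 10:
        raise MraError("need >= 10 samples for boosting inference")
    if len(tr_ids) < 2:
        raise MraError("need >= 2 candidate regulators")

    # canonical ordering so the result is invariant to input sample order
    data = m.data[sorted(m.sample_ids)]
    genes = list(data.index)
    x_all = _zscore_rows(data.to_numpy(dtype=float))
    row_of = {g: i for i, g in enumerate(genes)}
    tr_matrix = x_all[[row_of[t] for t in tr_ids]].T  # samples x TRs
    n = tr_matrix.shape[0]

    base = dict(
        objective="regression",
        learning_rate=params.learning_rate,
        max_depth=params.max_depth,
        num_leaves=max(2, 2 ** params.max_depth),
        bagging_fraction=params.row_subsample,
        bagging_freq=1,
        feature_fraction=params.regulator_subsample,
        min_data_in_leaf=max(2, min(20, n // 5)),
        verbose=-1,
        num_threads=1,
        deterministic=True,
        force_row_wise=True,
    )

    root = np.random.SeedSequence(params.seed)
    skipped = 0
    rows = []
    for gi, gene in enumerate(genes):
        y = x_all[row_of[gene]]
        if np.std(data.to_numpy()[row_of[gene]]) == 0.0:
            skipped += 1
            continue
        cand = [j for j, t in enumerate(tr_ids) if t != gene]
        if len(cand) < 2:
            raise MraError(f"fewer than 2 candidate regulators for {gene}")
        xm = tr_matrix[:, cand]
        ss = np.random.SeedSequence(entropy=root.entropy, spawn_key=(gi,))
        seeds = ss.generate_state(3)
        imp = _boost_importance(xm, y, base, params.n_rounds, int(seeds[0] % 2**31))
        rng = np.random.default_rng(seeds[1])
        imp_null = _boost_importance(
            xm, rng.permutation(y), base, params.n_rounds, int(seeds[2] % 2**31)
        )
        null_max = imp_null.max() if imp_null.size else 0.0
        # margin > 1 makes the permuted-target control an effective null:
        # a single comparison against the null maximum is a coin flip for a
        # pure-noise target, while true regulator gains sit far above it
        keep = imp > params.null_margin * null_max
        if not keep.any():
            continue
        mx = imp.max()
        rescaled = imp / mx
        keep &= rescaled >= params.theta
        idx = np.flatnonzero(keep)
        if idx.size > params.top_k:
            idx = idx[np.argsort(imp[idx], kind="stable")[::-1][: params.top_k]]
        for j in idx:
            rows.append((tr_ids[cand[j]], gene, float(rescaled[j])))
    if skipped:
        warnings.warn(f"skipped {skipped} zero-variance target row(s)")
    edges = pd.DataFrame(rows, columns=["regulator", "target", "weight"])
    return WeightedNetwork(edges, BOOSTING)


def _boost_importance(x: np.ndarray, y: np.ndarray, base: dict, n_rounds: int, seed: int) -> np.ndarray:
    p = dict(base, seed=seed, feature_fraction_seed=seed + 1, bagging_seed=seed + 2,
             data_random_seed=seed + 3)
    ds = lgb.Dataset(x, label=y, params={"verbose": -1})
    booster = lgb.train(p, ds, num_boost_round=n_rounds)
    return booster.feature_importance(importance_type="gain").astype(float)


# ---------------------------------------------------------------------------
# mutual information engine


def equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign equal-frequency bin labels; tied values share a bin."""
    n = x.size
    order = np.sort(x)
    cuts = [order[int(round(i * n / n_bins)) - 1: int(round(i * n / n_bins)) + 1].mean()
            for i in range(1, n_bins)]
    return np.searchsorted(np.asarray(cuts), x, side="right")


def plugin_mi_bits(counts: np.ndarray) -> float:
    """Plug-in mutual information (bits) from a joint contingency table."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / (px @ py)[nz])).sum())


def miller_madow_mi_bits(counts: np.ndarray) -> float:
    """Plug-in MI plus the Miller-Madow bias correction."""
    n = counts.sum()
    kx = int((counts.sum(axis=1) > 0).sum())
    ky = int((counts.sum(axis=0) > 0).sum())
    kxy = int((counts > 0).sum())
    corr = (kx + ky - kxy - 1) / (2.0 * n * np.log(2.0)) if n else 0.0
    return plugin_mi_bits(counts) + corr


def _joint_counts(bx: np.ndarray, by: np.ndarray, nbx: int, nby: int) -> np.ndarray:
    return np.bincount(bx * nby + by, minlength=nbx * nby).reshape(nbx, nby)


def pairwise_mutual_information(
    m: ExpressionMatrix,
    tr_ids: list[str],
    n_bins: int | None = None,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> WeightedNetwork:
    """MI network over all (TR, gene) pairs with a permutation keep-threshold.

    Rows are discretized into equal-frequency bins (default ceil(sqrt(N))
    capped at 10). An edge is kept when its Miller-Madow MI exceeds the
    (1 - alpha) quantile of MI under row permutation. The permutation null
    depends only on the two rows' bin-count profiles, so null thresholds are
    cached per profile pair. Constant rows have MI 0 and are dropped.
    """
    if m.n_samples < 8:
        raise MraError("need >= 8 samples for MI inference")
    tr_ids = sorted(set(tr_ids))
    missing = set(tr_ids) - set(m.gene_ids)
    if missing:
        raise MraError(f"TRs absent from matrix: {sorted(missing)[:5]}")
    n = m.n_samples
    if n_bins is None:
        n_bins = min(10, int(np.ceil(np.sqrt(n))))

    data = m.data[sorted(m.sample_ids)]
    genes = list(data.index)
    x = data.to_numpy(dtype=float)
    labels = {}
    counts1d = {}
    for i, g in enumerate(genes):
        if np.std(x[i]) == 0.0:
            continue
        b = equal_frequency_bins(x[i], n_bins)
        labels[g] = b
        counts1d[g] = tuple(sorted(np.bincount(b, minlength=n_bins)))

    rng = np.random.default_rng(seed)
    null_cache: dict[tuple, float] = {}

    def null_threshold(g1: str, g2: str) -> float:
        key = tuple(sorted((counts1d[g1], counts1d[g2])))
        if key not in null_cache:
            b1 = labels[g1]
            b2 = labels[g2].copy()
            vals = np.empty(n_perm)
            for p in range(n_perm):
                rng.shuffle(b2)
                vals[p] = miller_madow_mi_bits(_joint_counts(b1, b2, n_bins, n_bins))
            null_cache[key] = float(np.quantile(vals, 1.0 - alpha))
        return null_cache[key]

    rows = []
    for tr in tr_ids:
        if tr not in labels:
            continue
        btr = labels[tr]
        for g in genes:
            if g == tr or g not in labels:
                continue
            mi = miller_madow_mi_bits(_joint_counts(btr, labels[g], n_bins, n_bins))
            if mi > 0 and mi > null_threshold(tr, g):
                rows.append((tr, g, mi))
    edges = pd.DataFrame(rows, columns=["regulator", "target", "weight"])
    return WeightedNetwork(edges, MI)


def apply_dpi(net: WeightedNetwork, tolerance: float = 0.15) -> WeightedNetwork:
    """Data-processing-inequality pruning of MI networks.

    In every triangle, the edge (a,c) is removed when
    weight(a,c) <= (1 - tolerance) * min(weight(a,b), weight(b,c)),
    evaluated against the pre-pruning weights.
    """
    if net.engine != MI:
        raise MraError("DPI applies to MI networks only")
    e = net.edges
    w: dict[frozenset, float] = {}
    adj: dict[str, set[str]] = {}
    for reg, tgt, weight in zip(e["regulator"], e["target"], e["weight"]):
        w[frozenset((reg, tgt))] = float(weight)
        adj.setdefault(reg, set()).add(tgt)
        adj.setdefault(tgt, set()).add(reg)
    removed: set[frozenset] = set()
    for pair, wac in w.items():
        a, c = tuple(pair)
        for b in adj[a] & adj[c]:
            wab = w.get(frozenset((a, b)))
            wbc = w.get(frozenset((b, c)))
            if wab is None or wbc is None:
                continue
            if wac <= (1.0 - tolerance) * min(wab, wbc):
                removed.add(pair)
                break
    keep = [frozenset((r, t)) not in removed for r, t in zip(e["regulator"], e["target"])]
    return WeightedNetwork(e.loc[keep].reset_index(drop=True), MI)


def filter_regulons(net: WeightedNetwork, min_size: int = 10) -> WeightedNetwork:
    """Drop every edge of any TR with fewer than ``min_size`` targets."""
    if not len(net.edges):
        return WeightedNetwork(net.edges.copy(), net.engine)
    sizes = net.regulon_sizes()
    keep_tr = set(sizes.index[sizes >= min_size])
    keep = net.edges["regulator"].isin(keep_tr)
    return WeightedNetwork(net.edges.loc[keep].reset_index(drop=True), net.engine)


def sign_regulons(
    net: WeightedNetwork,
    m: ExpressionMatrix,
    min_regulon_size: int = 10,
) -> list[SignedRegulon]:
    """Assign per-target modes from Spearman correlation with the TR row.

    mode = sign(rho); confidence = (per-TR max-rescaled weight) * |rho|.
    Targets with rho = 0 or undefined are dropped, and the minimum regulon
    size is re-applied afterwards.
    """
    e = net.edges
    needed = sorted(set(e["regulator"]) | set(e["target"]))
    missing = [g for g in needed if g not in m.data.index]
    if missing:
        raise MraError(f"edge endpoints absent from matrix: {missing[:5]}")
    ranks = {g: rankdata(m.data.loc[g].to_numpy()) for g in needed}
    regulons: list[SignedRegulon] = []
    for tr, sub in e.groupby("regulator", sort=True):
        rt = ranks[tr]
        if np.std(rt) == 0.0:
            continue
        wmax = sub["weight"].max()
        targets, modes, conf = [], [], []
        for tgt, weight in zip(sub["target"], sub["weight"]):
            rg = ranks[tgt]
            if np.std(rg) == 0.0:
                continue
            rho = float(np.corrcoef(rt, rg)[0, 1])
            if rho == 0.0 or not np.isfinite(rho):
                continue
            targets.append(tgt)
            modes.append(1 if rho > 0 else -1)
            conf.append((weight / wmax) * abs(rho))
        if len(targets) >= min_regulon_size:
            regulons.append(
                SignedRegulon(tr, targets, np.array(modes, dtype=int), np.array(conf, dtype=float))
            )
    return regulons


def regulons_to_edge_table(regulons: list[SignedRegulon]) -> pd.DataFrame:
    rows = [
        (r.tr_id, t, c, m_, c)
        for r in regulons
        for t, m_, c in zip(r.targets, r.modes, r.confidence)
    ]
    return pd.DataFrame(rows, columns=["regulator", "target", "weight", "mode", "confidence"])


def regulons_from_edge_table(df: pd.DataFrame) -> list[SignedRegulon]:
    if "mode" not in df.columns:
        raise MraError("edge table lacks a mode column")
    conf_col = "confidence" if "confidence" in df.columns else "weight"
    out = []
    for tr, sub in df.groupby("regulator", sort=True):
        out.append(
            SignedRegulon(
                str(tr),
                [str(t) for t in sub["target"]],
                sub["mode"].to_numpy(dtype=int),
                sub[conf_col].to_numpy(dtype=float),
            )
        )
    return out
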