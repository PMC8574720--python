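"""Ground-truthed synthetic inputs: planted signed GRN, latent regulator
activities with group shifts, and target expression.

The generative model is linear-Gaussian. Each transcription regulator (TR)
has a latent per-sample activity a_t ~ Normal(mu, 1); for a differential TR
mu = +delta/2 in its favored phenotype group and -delta/2 in the other. The
TR's own expression row is a noisy copy of its activity, each target row is
sum_t mode * weight * a_t plus Gaussian noise, and a designated block of
signature filler genes is shifted upward in the HIGH group so the subtyping
stage can recover the labels. Values are modeled post-normalization (no
library-size or count-level noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import HIGH, LOW, ExpressionMatrix, GeneSetCollection, MraError, PhenotypeLabels
from .subtyping import ICR_SIGNATURE


@dataclass
class SimulationConfig:
    n_tr: int = 100
    n_targets: int = 1000
    n_samples_per_group: int = 60
    regulon_size_range: tuple[int, int] = (20, 50)
    fraction_negative_modes: float = 0.3
    fraction_differential: float = 0.2
    effect_size: float = 2.0          # delta, activity-shift units
    noise_sd: float = 0.5             # sigma on target rows
    tr_expression_noise_sd: float = 0.25
    n_cohorts: int = 1
    shared_core_size: int | None = None  # None: all differential TRs shared
    signature_shift: float = 2.0      # HIGH-group shift of the 20 signature genes
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tr", "n_targets", "n_samples_per_group", "n_cohorts"):
            if getattr(self, name) <= 0:
                raise MraError(f"{name} must be positive")
        if self.noise_sd <= 0:
            raise MraError("noise_sd must be > 0")
        lo, hi = self.regulon_size_range
        if lo < 1 or hi < lo:
            raise MraError("invalid regulon_size_range")
        if hi > self.n_targets:
            raise MraError("regulon size exceeds number of targets")
        if not 0 <= self.fraction_negative_modes <= 1:
            raise MraError("fraction_negative_modes must be in [0,1]")


@dataclass
class TrueNetwork:
    """Planted regulons plus the differential-TR ground truth."""

    regulons: dict[str, list[tuple[str, int, float]]]  # tr -> [(target, mode, weight)]
    differential: dict[str, tuple[float, str]] = field(default_factory=dict)  # tr -> (delta, HIGH|LOW)

    def __post_init__(self) -> None:
        for tr, targets in self.regulons.items():
            if not targets:
                raise MraError(f"empty regulon for {tr}")
            for _, mode, _ in targets:
                if mode not in (-1, 1):
                    raise MraError("modes must be -1 or +1")
        unknown = set(self.differential) - set(self.regulons)
        if unknown:
            raise MraError(f"differential TRs not in network: {sorted(unknown)}")

    @property
    def tr_ids(self) -> list[str]:
        return list(self.regulons)

    def edges(self) -> pd.DataFrame:
        rows = [
            (tr, tgt, w, m)
            for tr, targets in self.regulons.items()
            for tgt, m, w in targets
        ]
        return pd.DataFrame(rows, columns=["regulator", "target", "weight", "mode"])

    def differential_of(self, direction: str) -> list[str]:
        return sorted(t for t, (_, d) in self.differential.items() if d == direction)


def _tr_name(i: int) -> str:
    return f"TR{i + 1:04d}"


def _target_name(i: int) -> str:
    return f"G{i + 1:05d}"


def simulate_network(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> TrueNetwork:
    """Draw a planted signed network per the configured regulon geometry."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    targets = [_target_name(i) for i in range(cfg.n_targets)]
    lo, hi = cfg.regulon_size_range
    regulons: dict[str, list[tuple[str, int, float]]] = {}
    for i in range(cfg.n_tr):
        size = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(cfg.n_targets, size=size, replace=False)
        modes = np.where(rng.random(size) < cfg.fraction_negative_modes, -1, 1)
        weights = rng.uniform(0.5, 1.0, size=size)
        regulons[_tr_name(i)] = [
            (targets[t], int(m), float(w)) for t, m, w in zip(chosen, modes, weights)
        ]
    n_diff = int(round(cfg.fraction_differential * cfg.n_tr))
    diff_ids = rng.choice(cfg.n_tr, size=n_diff, replace=False)
    differential = {}
    for j, i in enumerate(sorted(diff_ids)):
        direction = HIGH if j < (n_diff + 1) // 2 else LOW
        differential[_tr_name(i)] = (cfg.effect_size, direction)
    return TrueNetwork(regulons, differential)


def simulate_expression(
    net: TrueNetwork,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    cohort_id: str = "cohort",
) -> tuple[ExpressionMatrix, PhenotypeLabels, pd.DataFrame]:
    """Generate expression, labels and the latent activity matrix."""
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n = cfg.n_samples_per_group
    samples = [f"{cohort_id}_S{i + 1:03d}" for i in range(2 * n)]
    groups = np.array([HIGH] * n + [LOW] * n)
    trs = net.tr_ids

    mu = np.zeros((len(trs), 2 * n))
    for r, tr in enumerate(trs):
        if tr in net.differential:
            delta, direction = net.differential[tr]
            shift = delta / 2.0
            mu[r] = np.where(groups == direction, shift, -shift)
    activity = mu + rng.standard_normal((len(trs), 2 * n))
    act_df = pd.DataFrame(activity, index=trs, columns=samples)

    tr_expr = activity + cfg.tr_expression_noise_sd * rng.standard_normal(activity.shape)

    targets = sorted({t for reg in net.regulons.values() for t, _, _ in reg})
    tgt_index = {t: i for i, t in enumerate(targets)}
    signal = np.zeros((len(targets), 2 * n))
    for r, tr in enumerate(trs):
        for tgt, mode, w in net.regulons[tr]:
            signal[tgt_index[tgt]] += mode * w * activity[r]
    tgt_expr = signal + cfg.noise_sd * rng.standard_normal(signal.shape)

    all_targets = [_target_name(i) for i in range(cfg.n_targets)]
    filler = [t for t in all_targets if t not in tgt_index]
    filler_expr = rng.standard_normal((len(filler), 2 * n))

    sig_shift = np.where(groups == HIGH, cfg.signature_shift, 0.0)
    sig_expr = rng.standard_normal((len(ICR_SIGNATURE), 2 * n)) + sig_shift

    data = pd.DataFrame(
        np.vstack([tr_expr, tgt_expr, filler_expr, sig_expr]),
        index=[*trs, *targets, *filler, *ICR_SIGNATURE],
        columns=samples,
    )
    labels = PhenotypeLabels(pd.Series(groups, index=samples), cohort_id=cohort_id)
    return ExpressionMatrix(data), labels, act_df


@dataclass
class Cohort:
    cohort_id: str
    network: TrueNetwork
    expression: ExpressionMatrix
    labels: PhenotypeLabels
    activities: pd.DataFrame


def make_benchmark(cfg: SimulationConfig) -> tuple[list[Cohort], pd.DataFrame]:
    """K cohorts sharing a configurable core of differential TRs.

    Returns the cohorts and a ground-truth manifest (tr, cohort, delta,
    direction, shared flag). Cohort networks are independent draws; the
    shared core keeps identical direction in every cohort, emulating
    pan-cohort master regulators.
    """
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(2 * cfg.n_cohorts + 1)
    base = simulate_network(cfg, np.random.default_rng(children[0]))
    diff_trs = sorted(base.differential)
    core_size = cfg.shared_core_size if cfg.shared_core_size is not None else len(diff_trs)
    if core_size > len(diff_trs):
        raise MraError("shared core larger than the differential TR count")
    # keep direction balance in the shared core
    high = base.differential_of(HIGH)
    low = base.differential_of(LOW)
    core = sorted(high[: (core_size + 1) // 2] + low[: core_size // 2])
    private = [t for t in diff_trs if t not in core]

    # each private differential TR belongs to exactly one cohort (round-robin)
    private_of = {k: [] for k in range(cfg.n_cohorts)}
    for j, t in enumerate(private):
        private_of[j % cfg.n_cohorts].append(t)

    cohorts: list[Cohort] = []
    manifest_rows = []
    for k in range(cfg.n_cohorts):
        cid = f"C{k + 1}"
        rng_net = np.random.default_rng(children[1 + 2 * k])
        rng_expr = np.random.default_rng(children[2 + 2 * k])
        net_k = simulate_network(cfg, rng_net)
        differential = {t: base.differential[t] for t in core + private_of[k]}
        net_k = TrueNetwork(net_k.regulons, differential)
        expr, labels, act = simulate_expression(net_k, cfg, rng_expr, cohort_id=cid)
        cohorts.append(Cohort(cid, net_k, expr, labels, act))
        for t, (delta, direction) in differential.items():
            manifest_rows.append((t, cid, delta, direction, t in core))
    manifest = pd.DataFrame(
        manifest_rows, columns=["tr", "cohort", "delta", "direction", "shared"]
    )
    return cohorts, manifest


def truth_regulon_gmt(net: TrueNetwork) -> GeneSetCollection:
    """Signed regulons as paired sets TR_pos / TR_neg for GMT export."""
    sets: dict[str, set[str]] = {}
    for tr, targets in net.regulons.items():
        pos = {t for t, m, _ in targets if m == 1}
        neg = {t for t, m, _ in targets if m == -1}
        if pos:
            sets[f"{tr}_pos"] = pos
        if neg:
            sets[f"{tr}_neg"] = neg
    return GeneSetCollection(sets)
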