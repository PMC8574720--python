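import numpy as np
import pytest

from mra.grn import SignedRegulon
from mra.simulate import SimulationConfig, TrueNetwork, simulate_expression, simulate_network


def regulons_from_truth(net: TrueNetwork) -> list[SignedRegulon]:
    """Planted regulons as signed regulons (mode/weight from the truth)."""
    return [
        SignedRegulon(
            tr,
            [t for t, _, _ in targets],
            np.array([m for _, m, _ in targets], dtype=int),
            np.array([w for _, _, w in targets], dtype=float),
        )
        for tr, targets in net.regulons.items()
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated cohort with planted differential TRs (shared by tests)."""
    cfg = SimulationConfig(
        n_tr=20,
        n_targets=150,
        n_samples_per_group=40,
        regulon_size_range=(10, 15),
        fraction_differential=0.2,
        seed=3,
    )
    net = simulate_network(cfg)
    expr, labels, act = simulate_expression(net, cfg)
    return cfg, net, expr, labels, act
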