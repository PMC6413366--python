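import numpy as np
import pytest

from ploidyflow.cellcycle import CellCycleFit, CycleParams


@pytest.fixture
def make_fit():
    """Factory for hand-built cell-cycle fits (for decision-tree tests)."""

    def _make(
        cycles,
        debris_fraction=0.05,
        rcs=1.0,
        n_events=10_000,
        ambiguous=False,
    ):
        params = []
        total = sum(c.get("cycle_fraction", 1.0) for c in cycles)
        for c in cycles:
            params.append(
                CycleParams(
                    mu_g1=c["mu"],
                    cv_g1=c.get("cv", 4.0),
                    g2_ratio=c.get("g2_ratio", 2.0),
                    frac_g1=c.get("frac_g1", 0.85),
                    frac_s=c.get("frac_s", 0.05),
                    frac_g2m=c.get("frac_g2m", 0.10),
                    cycle_fraction=c.get("cycle_fraction", 1.0) / total,
                )
            )
        params.sort(key=lambda p: p.mu_g1)
        return CellCycleFit(
            cycles=params,
            debris_fraction=debris_fraction,
            rcs=rcs,
            n_events_fit=n_events,
            ambiguous=ambiguous,
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
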