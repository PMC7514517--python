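import numpy as np
import pytest

from maxentpop import (
    GeneratorConfig,
    PlantedSpec,
    TUYearRecord,
    generate_panel,
    generate_planted_panel,
)


def make_records(b, u, ce=None, cw=None, year=2000):
    """Self-consistent TU-year records from population and flow totals."""
    n = len(b)
    ce = ce if ce is not None else [1000.0 * x for x in b]
    cw = cw if cw is not None else [60.0 * x for x in b]
    return [
        TUYearRecord(tu_id=f"TU{i+1:02d}", year=year, b=float(b[i]), u=float(u[i]),
                     ce=float(ce[i]), cw=float(cw[i]))
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def realistic_panel():
    """33-TU noise-free panel with heavy-tailed shares and linear growth."""
    return generate_panel(GeneratorConfig(seed=7, years=(1999, 2010)))


@pytest.fixture(scope="session")
def planted_panel():
    """Planted-truth panel: 5 moments, trending targets, exact recovery in
    current-reference calibration."""
    cfg = GeneratorConfig(seed=42, years=(1999, 2015), integer_counts=False)
    return generate_planted_panel(cfg, PlantedSpec(m_max=5, drift=0.15))


@pytest.fixture(scope="session")
def planted_linear_panel():
    """Planted panel whose shares, totals and moment targets are exactly
    linear in the year (constant national population)."""
    cfg = GeneratorConfig(seed=42, years=(1999, 2015), integer_counts=False)
    return generate_planted_panel(
        cfg, PlantedSpec(m_max=5, drift=0.15, truth_mode="linear")
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
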