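import numpy as np
import pandas as pd
import pytest

from exmort import ScenarioConfig, Wave, compute_cdr, generate_panel

REF_YEARS = list(range(2015, 2020))


def rates_frame(cdr_fn, years=REF_YEARS, unit_id="RU", extra_years=()):
    """Build a single-unit RateSeries frame from cdr_fn(year, month)."""
    rows = [
        {"unit_id": unit_id, "year": t, "month": m, "cdr": float(cdr_fn(t, m))}
        for t in list(years) + list(extra_years)
        for m in range(1, 13)
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_panel():
    """3-unit noiseless panel: declining trend, one unit with a Q4 wave."""
    cfg = ScenarioConfig(
        n_units=3,
        trend_per_year=-15.0,
        waves={0: [Wave(8, 11, 12, 800.0)]},
        noise="none",
        seed=7,
    )
    panel, truth = generate_panel(cfg)
    return panel, truth, cfg


@pytest.fixture
def tiny_rates(tiny_panel):
    panel, truth, cfg = tiny_panel
    return compute_cdr(panel), truth, cfg


@pytest.fixture
def noisy_unit_panel():
    """Single-unit Poisson panel with a known injected annual excess."""
    cfg = ScenarioConfig(
        n_units=1,
        trend_per_year=-10.0,
        waves={0: [Wave(3, 8, 12, 500.0)]},
        exposure=1_000_000.0,
        seed=42,
    )
    panel, truth = generate_panel(cfg)
    return panel, truth, cfg
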