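"""Shared fixtures. Full-scenario ring simulations are expensive (~5-10 s
each), so they are run once per session and shared across test modules."""

from __future__ import annotations

import pytest

from mzring import ModelParams, ScenarioConfig, simulate


@pytest.fixture(scope="session")
def intact_records():
    """Intact-scenario records for both production modes."""
    out = {}
    for mode in ("heaviside", "hill"):
        params = ModelParams(production_mode=mode)
        out[mode] = simulate(ScenarioConfig(scenario="intact"), params)
    return out


@pytest.fixture(scope="session")
def half_records():
    """Anterior-half records keyed by (production_mode, obliquity_offset)."""
    out = {}
    for mode in ("heaviside", "hill"):
        for offset in (2, -2, 1):
            params = ModelParams(production_mode=mode)
            config = ScenarioConfig(scenario="anterior_half",
                                    obliquity_offset=offset)
            out[(mode, offset)] = simulate(config, params)
    return out
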