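"""Shared fixtures: small synthetic cohorts and fitted pipeline pieces.

Session-scoped so the expensive pieces (window fit, GP hyperparameters)
are computed once per run.
"""

from __future__ import annotations

import pytest

from sepsiswatch.ctwh import build_window_config
from sepsiswatch.mgp import MgpConfig, fit_hyperparameters
from sepsiswatch.panel import default_panel
from sepsiswatch.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort(panel):
    """60 episodes, default study conditions."""
    return generate_cohort(CohortSpec(n_patients=60, seed=42), panel)


@pytest.fixture(scope="session")
def windows(small_cohort, panel):
    return build_window_config(small_cohort, panel)


@pytest.fixture(scope="session")
def mgp_cfg():
    return MgpConfig()


@pytest.fixture(scope="session")
def hypers(small_cohort, panel, windows, mgp_cfg):
    return fit_hyperparameters(small_cohort, panel, windows, mgp_cfg, seed=0)
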