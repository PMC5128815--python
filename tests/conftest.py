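"""Shared fixtures: expensive simulated cohorts and fitted models are
session-scoped so module tests and acceptance tests reuse them."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from seqdx.expression import ExpressionMatrix, normalize_log_cpm
from seqdx.grade import TgCvConfig, fit_tg_model
from seqdx.synthetic import CohortConfig, generate_cohort

STRONG_CONFIG = CohortConfig(n_samples=400, marker_shift=2.0, noise_sd=1.0,
                             grade_effect=1.5, discordance_rate=0.0, seed=0)
NULL_CONFIG = CohortConfig(n_samples=400, marker_shift=0.0, noise_sd=1.0,
                           discordance_rate=0.0, seed=0)
MIXTURE_CONFIG = CohortConfig(n_samples=500, grade_effect=1.5, grade2_mixture=True,
                              grade_weights={1: 0.25, 2: 0.5, 3: 0.25},
                              discordance_rate=0.0, seed=0)
TG_CV = TgCvConfig(n_lambda=20, seed=0)


def _subcomponents(clinical: pd.DataFrame) -> pd.DataFrame:
    return clinical.rename(columns={
        "mitotic_score": "mitotic",
        "nuclear_atypia_score": "nuclear_atypia",
        "tubular_formation_score": "tubular_formation",
    })[["mitotic", "nuclear_atypia", "tubular_formation"]]


@pytest.fixture(scope="session")
def strong_cohort():
    return generate_cohort(STRONG_CONFIG)


@pytest.fixture(scope="session")
def strong_normalized(strong_cohort):
    return normalize_log_cpm(strong_cohort.expression)


@pytest.fixture(scope="session")
def strong_tg_model(strong_cohort, strong_normalized):
    return fit_tg_model(strong_normalized, _subcomponents(strong_cohort.clinical),
                        strong_cohort.clinical["grade"], TG_CV)


@pytest.fixture(scope="session")
def null_cohort():
    return generate_cohort(NULL_CONFIG)


@pytest.fixture(scope="session")
def mixture_cohort():
    return generate_cohort(MIXTURE_CONFIG)


@pytest.fixture(scope="session")
def mixture_tg_model(mixture_cohort):
    m = normalize_log_cpm(mixture_cohort.expression)
    model = fit_tg_model(m, _subcomponents(mixture_cohort.clinical),
                         mixture_cohort.clinical["grade"], TG_CV)
    return m, model


@pytest.fixture()
def random_log2_matrix():
    def make(n_genes=10, n_samples=40, seed=0):
        rng = np.random.default_rng(seed)
        vals = pd.DataFrame(rng.normal(5.0, 1.0, (n_genes, n_samples)),
                            index=[f"g{i}" for i in range(n_genes)],
                            columns=[f"s{i}" for i in range(n_samples)])
        return ExpressionMatrix(vals, scale="log2")
    return make
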