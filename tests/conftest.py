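import pandas as pd
import pytest

from foodbench.commitment_scoring import WeightTable, score_frame
from foodbench.nutrient_profiling import NOVARules, WHORuleTable, profile_products
from foodbench.portfolio_indicators import summarize_portfolios
from foodbench.synthetic_data import (
    StudyConfig,
    generate_commitments,
    generate_companies,
    generate_portfolios,
)

N_PAPER = {"manufacturer": 19, "supermarket": 5, "quick_service": 7}


@pytest.fixture(scope="session")
def who_rules() -> WHORuleTable:
    return WHORuleTable.default()


@pytest.fixture(scope="session")
def nova_rules() -> NOVARules:
    return NOVARules.default()


@pytest.fixture(scope="session")
def uniform_weights() -> WeightTable:
    return WeightTable.uniform()


@pytest.fixture(scope="session")
def linkage_study(who_rules, nova_rules, uniform_weights):
    """Factory: generate one synthetic study and return the frames the
    linkage analysis consumes (pre-engagement scores + portfolio
    summaries), plus the latent companies."""

    def _make(
        seed: int,
        coupling: float,
        noise_sd: float,
        portfolio_size_range=(10, 60),
        n_companies=N_PAPER,
        stage: str = "public_only",
    ):
        config = StudyConfig(
            seed=seed,
            coupling=coupling,
            noise_sd=noise_sd,
            portfolio_size_range=portfolio_size_range,
            n_companies=n_companies,
        )
        companies = generate_companies(config)
        profiled = profile_products(
            generate_portfolios(config, companies), who_rules, nova_rules
        )
        summaries, _ = summarize_portfolios(profiled)
        bia = score_frame(generate_commitments(config, companies), uniform_weights)
        return bia[bia["stage"] == stage].reset_index(drop=True), summaries, companies

    return _make


@pytest.fixture(scope="session")
def demo_bundle(who_rules):
    """One small default study bundle, shared across read-only tests."""
    from foodbench.synthetic_data import generate_study

    config = StudyConfig(
        seed=42,
        n_companies={"manufacturer": 6, "supermarket": 3, "quick_service": 3},
        portfolio_size_range=(5, 25),
        n_flyer_weeks=8,
    )
    return generate_study(config, who_rules=who_rules)
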