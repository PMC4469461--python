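"""Shared fixtures and hypothesis settings for the ivmr test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ivmr.summary_data import HarmonizedPair, InstrumentSet, SnpAssociation

# Deterministic hypothesis runs: failures must reproduce bit-for-bit.
settings.register_profile(
    "ivmr",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ivmr")

SEED = 1234


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)


def make_pair(
    rsid: str = "rs1",
    beta_exposure: float = 0.1,
    se_exposure: float = 0.01,
    beta_outcome: float = -0.03,
    se_outcome: float = 0.02,
    **kwargs,
) -> HarmonizedPair:
    return HarmonizedPair(
        rsid=rsid,
        beta_exposure=beta_exposure,
        se_exposure=se_exposure,
        beta_outcome=beta_outcome,
        se_outcome=se_outcome,
        **kwargs,
    )


def make_set(pairs, trait_name="trait", trait_type="continuous",
             unit_label="1 SD", unit_scale=1.0) -> InstrumentSet:
    return InstrumentSet(
        trait_name=trait_name,
        trait_type=trait_type,
        unit_label=unit_label,
        unit_scale=unit_scale,
        pairs=tuple(pairs),
    )


def random_instrument_set(rng: np.random.Generator, n_snps: int) -> InstrumentSet:
    """An instrument set with positive exposure effects and noisy ratios."""
    pairs = []
    for j in range(n_snps):
        pairs.append(
            make_pair(
                rsid=f"rs{j + 1}",
                beta_exposure=float(rng.uniform(0.02, 0.3)),
                se_exposure=float(rng.uniform(0.005, 0.02)),
                beta_outcome=float(rng.normal(0, 0.05)),
                se_outcome=float(rng.uniform(0.01, 0.1)),
            )
        )
    return make_set(pairs)


@pytest.fixture
def snp_a() -> SnpAssociation:
    return SnpAssociation(
        rsid="rs1", effect_allele="A", other_allele="G", beta=0.1, se=0.02, eaf=0.3
    )
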