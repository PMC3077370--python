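"""Shared fixtures: small seeded synthetic datasets and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from alrexscan.simulate import SyntheticConfig, gen_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small default-structure synthetic dataset (120 + 120 transcripts)."""
    cfg = SyntheticConfig(n_pos=120, n_neg=120, seed=7)
    records, ledger = gen_dataset(cfg)
    return cfg, records, ledger


@pytest.fixture(scope="session")
def medium_dataset():
    """The n = 500 per class study-condition dataset used for recovery checks."""
    cfg = SyntheticConfig(n_pos=500, n_neg=500, seed=1)
    records, ledger = gen_dataset(cfg)
    return cfg, records, ledger


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_cds(rng: np.random.Generator, n_codons: int = 100) -> str:
    """Random in-frame CDS: ATG + sense codons + TAA."""
    from alrexscan.simulate import SENSE_CODONS

    body = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"
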