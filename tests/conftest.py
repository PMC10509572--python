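"""Shared fixtures: small handcrafted and simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from ypopgen import (
    PopulationDataset,
    SampleRecord,
    YHaplotype,
    default_config,
    default_panel,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def make_sample(
    panel,
    sample_id: str,
    alleles: dict[str, tuple[float, ...]] | None = None,
    population: str = "PopA",
    ethnicity: str = "Han",
    haplogroup: str = "O2-M122",
    latitude: float = 34.0,
    longitude: float = 113.0,
    base_offset: float = 0.0,
) -> SampleRecord:
    """A fully-typed record; unspecified loci get fixed default alleles."""
    full: dict[str, tuple[float, ...] | None] = {}
    for loc in panel.loci:
        if alleles and loc.name in alleles:
            call = alleles[loc.name]
            full[loc.name] = None if call is None else tuple(sorted(float(v) for v in call))
        else:
            base = 12.0 + base_offset
            full[loc.name] = tuple(sorted([base] * loc.copy_number))
    return SampleRecord(
        sample_id=sample_id,
        population=population,
        ethnicity=ethnicity,
        latitude=latitude,
        longitude=longitude,
        haplogroup=haplogroup,
        haplotype=YHaplotype(alleles=full),
    )


@pytest.fixture()
def make_record(panel):
    def _make(sample_id, **kw):
        return make_sample(panel, sample_id, **kw)

    return _make


@pytest.fixture(scope="session")
def sim_dataset():
    """A small study-shaped simulated dataset (about 100 males, 5 groups)."""
    cfg = default_config(seed=11, scale=0.03)
    ds, truth, snp_states = simulate_dataset(cfg)
    return ds, truth, snp_states


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
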