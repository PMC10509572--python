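"""Diversity statistics: formula correctness, invariants, oracle agreement."""

from __future__ import annotations

import numpy as np
import pytest

from ypopgen import (
    PopulationDataset,
    discrimination_capacity,
    diversity,
    frequency_spectrum,
    haplogroup_frequency_table,
    match_probability,
    per_locus_gene_diversity,
    population_summary,
)
from ypopgen.diversity import (
    UndefinedStatisticError,
    spectrum_from_values,
)
from conftest import make_sample


def spec_from_counts(counts):
    values = []
    for i, c in enumerate(counts):
        values.extend([f"cat{i}"] * c)
    return spectrum_from_values(values, "haplotype")


class TestDiversityFormula:
    def test_monomorphic_is_zero(self):
        assert diversity(spec_from_counts([10])).value == 0.0

    def test_all_singletons_is_one(self):
        assert diversity(spec_from_counts([1] * 10)).value == pytest.approx(1.0)

    def test_hand_example(self):
        # n=4, counts {2,1,1}: 4(1 - 0.375)/3
        assert diversity(spec_from_counts([2, 1, 1])).value == pytest.approx(5.0 / 6.0)

    def test_requires_two_samples(self):
        with pytest.raises(UndefinedStatisticError):
            diversity(spec_from_counts([1]))

    def test_identity_with_match_probability(self, rng):
        """diversity = (1 - MP) * n/(n-1) exactly, for any spectrum."""
        for _ in range(50):
            counts = rng.integers(1, 6, size=rng.integers(1, 8)).tolist()
            spec = spec_from_counts(counts)
            if spec.n < 2:
                continue
            d = diversity(spec)
            mp = match_probability(spec)
            assert d.value == pytest.approx((1 - mp) * spec.n / (spec.n - 1), abs=1e-12)


class TestDCandMP:
    def test_dc_examples(self):
        assert discrimination_capacity(spec_from_counts([1, 1, 1, 1])) == 1.0
        assert discrimination_capacity(spec_from_counts([2, 1, 1])) == 0.75

    def test_dc_requires_haplotype_kind(self):
        spec = spectrum_from_values(["a", "b"], "allele")
        with pytest.raises(ValueError):
            discrimination_capacity(spec)

    def test_mp_examples(self):
        assert match_probability(spec_from_counts([7])) == 1.0
        assert match_probability(spec_from_counts([1, 1, 1, 1])) == 0.25

    def test_all_unique_iff_mp_is_reciprocal_n(self, rng):
        for _ in range(20):
            counts = rng.integers(1, 4, size=rng.integers(2, 6)).tolist()
            spec = spec_from_counts(counts)
            dc = discrimination_capacity(spec)
            assert (dc == 1.0) == (match_probability(spec) == pytest.approx(1 / spec.n))


class TestSpectra:
    def test_haplogroup_level0_direct_counting(self, panel):
        samples = [
            make_sample(panel, f"S{i}", haplogroup="O2-M122" if i < 8 else "C2a-L1373")
            for i in range(10)
        ]
        ds = PopulationDataset(panel=panel, samples=samples)
        spec = frequency_spectrum(ds, key="haplogroup", level=0)
        assert spec.frequencies() == {"O": 0.8, "C": 0.2}

    def test_haplotype_spectrum_merges_identical(self, panel):
        samples = [
            make_sample(panel, "S1"),
            make_sample(panel, "S2"),
            make_sample(panel, "S3", base_offset=1),
            make_sample(panel, "S4", base_offset=2),
        ]
        ds = PopulationDataset(panel=panel, samples=samples)
        spec = frequency_spectrum(ds, key="haplotype")
        assert sorted(spec.categories.values()) == [1, 1, 2]

    def test_pooling_invariance(self, sim_dataset):
        """Pooled frequencies equal count-weighted means of subpopulation ones."""
        ds, _, _ = sim_dataset
        pooled = frequency_spectrum(ds, key="haplogroup", level=0)
        combined: dict[str, float] = {}
        for pop in ds.populations:
            sub = ds.subset(population=pop)
            spec = frequency_spectrum(sub, key="haplogroup", level=0)
            for k, f in spec.frequencies().items():
                combined[k] = combined.get(k, 0.0) + f * spec.n
        for k, f in pooled.frequencies().items():
            assert combined[k] / pooled.n == pytest.approx(f)

    def test_missing_data_excluded_from_statistic_only(self, panel):
        samples = [make_sample(panel, f"S{i}") for i in range(3)]
        samples.append(make_sample(panel, "S3", alleles={"DYS391": None}))
        ds = PopulationDataset(panel=panel, samples=samples)
        spec = frequency_spectrum(ds, key="allele", locus="DYS391")
        assert spec.n == 3 and spec.n_excluded == 1
        # the same sample still counts at other loci
        assert frequency_spectrum(ds, key="allele", locus="DYS19").n == 4


class TestPerLocusGD:
    def test_monomorphic_locus_zero(self, panel):
        ds = PopulationDataset(panel=panel, samples=[make_sample(panel, f"S{i}") for i in range(20)])
        gd = per_locus_gene_diversity(ds)
        assert (gd["gd"] == 0.0).all()

    def test_multicopy_combination_is_category(self, panel):
        samples = [
            make_sample(panel, "S1", alleles={"DYS385": (11, 14)}),
            make_sample(panel, "S2", alleles={"DYS385": (14, 11)}),
            make_sample(panel, "S3", alleles={"DYS385": (11, 15)}),
            make_sample(panel, "S4", alleles={"DYS385": (11, 15)}),
        ]
        ds = PopulationDataset(panel=panel, samples=samples)
        gd = per_locus_gene_diversity(ds).set_index("locus")
        # two combination categories with counts {2, 2}
        assert gd.loc["DYS385", "n_alleles"] == 2
        assert gd.loc["DYS385", "gd"] == pytest.approx(4 * (1 - 0.5) / 3)


class TestSummaries:
    def test_population_summary_shape(self, sim_dataset):
        ds, _, _ = sim_dataset
        summary = population_summary(ds, by="ethnicity")
        assert set(summary["ethnicity"]) == set(ds.ethnicities) | {"all"}
        assert (summary["haplotype_diversity"] <= 1.0).all()
        assert (summary["match_probability"] > 0).all()

    def test_frequency_table_rows_sum_to_one(self, sim_dataset):
        ds, _, _ = sim_dataset
        table = haplogroup_frequency_table(ds, level=0)
        assert np.allclose(table.sum(axis=1), 1.0)
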