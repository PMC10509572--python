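"""AMOVA FST, PCA and IDW surface behaviour."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ypopgen import (
    PopulationDataset,
    idw_surface,
    pairwise_fst,
    pca_haplogroup_freq,
)
from ypopgen.structure import _amova_fst
from conftest import make_sample


def two_pop_dataset(panel, alleles_a, alleles_b, locus="DYS391"):
    """Two populations differing only at one locus; one value per sample."""
    samples = []
    for i, v in enumerate(alleles_a):
        samples.append(make_sample(panel, f"A{i}", population="PopA", alleles={locus: (v,)}))
    for i, v in enumerate(alleles_b):
        samples.append(make_sample(panel, f"B{i}", population="PopB", alleles={locus: (v,)}))
    return PopulationDataset(panel=panel, samples=samples)


def brute_force_amova(d2, sizes):
    """Definitional AMOVA: naive double loops over all pairs."""
    n = d2.shape[0]
    p = len(sizes)
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d2[i, j]
    ss_total /= n
    ss_within = 0.0
    start = 0
    for nk in sizes:
        s = 0.0
        for i in range(start, start + nk):
            for j in range(i + 1, start + nk):
                s += d2[i, j]
        ss_within += s / nk
        start += nk
    ms_among = (ss_total - ss_within) / (p - 1)
    ms_within = ss_within / (n - p)
    n_prime = (n - sum(nk**2 for nk in sizes) / n) / (p - 1)
    sigma_a = (ms_among - ms_within) / n_prime
    if sigma_a + ms_within == 0:
        return 0.0
    return sigma_a / (sigma_a + ms_within)


class TestFst:
    def test_identical_populations_near_zero(self, panel):
        ds = two_pop_dataset(panel, [10, 11, 12, 13], [10, 11, 12, 13])
        dm = pairwise_fst(ds, n_permutations=99, seed=1)
        # identical multisets: the raw AMOVA estimate carries the usual
        # small-sample negative bias; no among-group variance remains
        assert dm.values[0, 1] <= 1e-9
        assert dm.clipped()[0, 1] == 0.0
        assert dm.pvalues[0, 1] > 0.5

    def test_fixed_difference_is_one(self, panel):
        ds = two_pop_dataset(panel, [10, 10, 10], [14, 14, 14])
        for mode in ("haplotype_identity", "stepwise"):
            dm = pairwise_fst(ds, mode=mode, n_permutations=99, seed=1)
            assert dm.values[0, 1] == pytest.approx(1.0)

    def test_agrees_with_definitional_oracle(self, panel, rng):
        for _ in range(10):
            na, nb = rng.integers(2, 7), rng.integers(2, 7)
            ds = two_pop_dataset(
                panel,
                rng.integers(10, 14, size=na).tolist(),
                rng.integers(10, 14, size=nb).tolist(),
            )
            dm = pairwise_fst(ds, mode="stepwise", n_permutations=0, seed=0)
            from ypopgen.structure import _squared_distances

            d2 = _squared_distances(ds, list(range(na + nb)), "stepwise")
            assert dm.values[0, 1] == pytest.approx(brute_force_amova(d2, [na, nb]), abs=1e-9)

    def test_symmetry_and_label_invariance(self, panel, rng):
        ds = two_pop_dataset(panel, [10, 11, 12], [12, 13, 14])
        dm = pairwise_fst(ds, n_permutations=49, seed=7)
        assert dm.values[0, 1] == dm.values[1, 0]
        assert np.all(np.diag(dm.values) == 0)
        # sample order within populations does not change the estimate
        ds2 = two_pop_dataset(panel, [12, 11, 10], [14, 13, 12])
        dm2 = pairwise_fst(ds2, n_permutations=49, seed=7)
        assert dm2.values[0, 1] == pytest.approx(dm.values[0, 1])

    def test_stepwise_reduces_to_identity_when_equidistant(self, panel):
        """All-distinct, mutually equidistant haplotypes: both modes agree."""
        samples = []
        for i, (pop, locus) in enumerate(
            [("PopA", "DYS391"), ("PopA", "DYS393"), ("PopB", "DYS439"), ("PopB", "DYS437")]
        ):
            samples.append(
                make_sample(panel, f"S{i}", population=pop, alleles={locus: (13.0,)})
            )
        ds = PopulationDataset(panel=panel, samples=samples)
        a = pairwise_fst(ds, mode="haplotype_identity", n_permutations=0).values[0, 1]
        b = pairwise_fst(ds, mode="stepwise", n_permutations=0).values[0, 1]
        assert a == pytest.approx(b)

    def test_skips_undersized_population(self, panel):
        samples = [make_sample(panel, "A0", population="PopA")]
        samples += [make_sample(panel, f"B{i}", population="PopB") for i in range(3)]
        ds = PopulationDataset(panel=panel, samples=samples)
        with pytest.warns(UserWarning, match="fewer than 2"):
            dm = pairwise_fst(ds, n_permutations=9, seed=0)
        assert np.isnan(dm.values[0, 1])


class TestPCA:
    def test_identical_rows_project_together(self):
        fm = pd.DataFrame(
            [[0.5, 0.5], [0.5, 0.5], [0.9, 0.1]], index=["a", "b", "c"], columns=["O", "C"]
        )
        res = pca_haplogroup_freq(fm, n_components=1)
        assert res.coordinates.loc["a", "PC1"] == pytest.approx(res.coordinates.loc["b", "PC1"])

    def test_explained_variance_sums_to_one(self):
        rng = np.random.default_rng(0)
        fm = pd.DataFrame(rng.dirichlet(np.ones(4), size=5))
        res = pca_haplogroup_freq(fm, n_components=4)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_gradient_orders_pc1(self):
        fm = pd.DataFrame(
            {"O": [0.1, 0.5, 0.9], "C": [0.9, 0.5, 0.1]}, index=["p1", "p2", "p3"]
        )
        res = pca_haplogroup_freq(fm, n_components=1)
        pc1 = res.coordinates["PC1"]
        assert pc1["p1"] < pc1["p2"] < pc1["p3"]

    def test_constant_matrix_warns_zero(self):
        fm = pd.DataFrame([[0.5, 0.5]] * 3)
        with pytest.warns(UserWarning, match="zero variance"):
            res = pca_haplogroup_freq(fm, n_components=1)
        assert np.all(res.coordinates.to_numpy() == 0)


class TestIDW:
    def test_single_station_uniform(self):
        surf = idw_surface([(30.0, 100.0, 0.4)], cell_size=1.0, padding=2.0)
        assert np.allclose(surf.values, 0.4)

    def test_exact_at_station(self):
        surf = idw_surface([(30.0, 100.0, 0.2), (34.0, 104.0, 0.8)], cell_size=1.0)
        i = np.argmin(np.abs(surf.lat - 30.0))
        j = np.argmin(np.abs(surf.lon - 100.0))
        assert surf.values[i, j] == pytest.approx(0.2)

    def test_midpoint_averages_equal_weights(self):
        surf = idw_surface([(30.0, 100.0, 0.2), (32.0, 100.0, 0.6)], cell_size=0.5)
        i = np.argmin(np.abs(surf.lat - 31.0))
        j = np.argmin(np.abs(surf.lon - 100.0))
        assert surf.values[i, j] == pytest.approx(0.4)

    def test_bounded_by_station_range(self):
        stations = [(30.0, 100.0, 0.1), (33.0, 103.0, 0.7), (36.0, 99.0, 0.3)]
        surf = idw_surface(stations, cell_size=0.5)
        assert surf.values.min() >= 0.1 - 1e-12
        assert surf.values.max() <= 0.7 + 1e-12

    def test_conflicting_duplicate_stations_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            idw_surface([(30.0, 100.0, 0.1), (30.0, 100.0, 0.5)])
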