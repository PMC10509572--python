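"""TMRCA estimators: modal haplotype, ASD, rho, and the coalescent MCMC."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import ive

from ypopgen import (
    CharacterSet,
    MCMCConfig,
    MCMCPriors,
    PopulationDataset,
    asd_tmrca,
    build_mj_network,
    coalescent_mcmc_tmrca,
    modal_haplotype,
    rho_tmrca,
)
from conftest import make_sample


@pytest.fixture(scope="module")
def slow_rates():
    from ypopgen import default_panel

    panel = default_panel()
    return panel.mutation_rates(panel.slow)


def dataset_from_alleles(panel, per_sample: list[dict[str, float]]):
    samples = [
        make_sample(panel, f"S{i}", alleles={k: (v,) for k, v in row.items()})
        for i, row in enumerate(per_sample)
    ]
    return PopulationDataset(panel=panel, samples=samples)


class TestModalHaplotype:
    def test_majority(self, panel):
        ds = dataset_from_alleles(
            panel,
            [{"DYS391": 13, "DYS392": 29}, {"DYS391": 13, "DYS392": 29}, {"DYS391": 14, "DYS392": 29}],
        )
        modal = modal_haplotype(ds, ("DYS391", "DYS392"))
        assert modal.single_value("DYS391") == 13 and modal.single_value("DYS392") == 29

    def test_tie_breaks_to_smaller(self, panel):
        ds = dataset_from_alleles(panel, [{"DYS391": 13}, {"DYS391": 14}])
        assert modal_haplotype(ds, ("DYS391",)).single_value("DYS391") == 13

    def test_single_sample(self, panel):
        ds = dataset_from_alleles(panel, [{"DYS391": 11}])
        assert modal_haplotype(ds, ("DYS391",)).single_value("DYS391") == 11

    def test_all_missing_locus_named(self, panel):
        ds = PopulationDataset(
            panel=panel, samples=[make_sample(panel, "S1", alleles={"DYS391": None})]
        )
        with pytest.raises(ValueError, match="DYS391"):
            modal_haplotype(ds, ("DYS391",))


class TestASD:
    def test_zero_distance(self, panel, slow_rates):
        ds = dataset_from_alleles(panel, [{}] * 5)
        est = asd_tmrca(ds, slow_rates, seed=1, n_bootstrap=50)
        assert est.generations == 0.0 and est.years == 0.0

    def test_single_locus_hand_example(self, panel):
        # two samples both 2 repeats above the founder at one locus, mu=0.004
        ds = dataset_from_alleles(panel, [{"DYS391": 14}, {"DYS391": 14}])
        founder = modal_haplotype(dataset_from_alleles(panel, [{"DYS391": 12}]), ("DYS391",))
        est = asd_tmrca(
            ds, {"DYS391": 0.004}, loci=("DYS391",), founder=founder, seed=0, n_bootstrap=10
        )
        assert est.generations == pytest.approx(1000.0)
        assert est.years == pytest.approx(25_000.0)

    def test_translation_invariance(self, panel, slow_rates):
        rows = [{"DYS391": 11 + (i % 3), "DYS392": 13} for i in range(6)]
        shifted = [{k: v + 3 for k, v in r.items()} for r in rows]
        loci = ("DYS391", "DYS392")
        e1 = asd_tmrca(dataset_from_alleles(panel, rows), slow_rates, loci=loci, seed=2, n_bootstrap=10)
        e2 = asd_tmrca(dataset_from_alleles(panel, shifted), slow_rates, loci=loci, seed=2, n_bootstrap=10)
        assert e1.generations == pytest.approx(e2.generations)

    def test_years_ratio_is_generation_time(self, panel, slow_rates):
        ds = dataset_from_alleles(panel, [{"DYS391": 11}, {"DYS391": 13}])
        est = asd_tmrca(ds, slow_rates, loci=("DYS391",), seed=3, n_bootstrap=10)
        assert est.years == pytest.approx(est.generations * est.generation_time)


def star_network(n_tips: int):
    """Star: root at origin plus tips one step away on distinct characters."""
    chars = CharacterSet(
        names=tuple(f"L{i}" for i in range(n_tips)),
        weights=(1.0,) * n_tips,
        is_snp=(False,) * n_tips,
    )
    root = tuple(10.0 for _ in range(n_tips))
    classes = [(root, 1)]
    for i in range(n_tips):
        v = list(root)
        v[i] += 1
        classes.append((tuple(v), 1))
    return build_mj_network(classes, chars), root, chars


class TestRho:
    def test_zero_when_all_at_root(self):
        chars = CharacterSet(names=("a", "b"), weights=(1.0, 1.0), is_snp=(False, False))
        net = build_mj_network([((10.0, 10.0), 4)], chars)
        est = rho_tmrca(net, (10.0, 10.0), {"a": 0.01, "b": 0.02})
        assert est.generations == 0.0

    def test_star_hand_example(self):
        net, root, chars = star_network(5)
        rates = {name: 0.006 for name in chars.names}  # total 0.03
        est = rho_tmrca(net, root, rates)
        # rho = 5/6 over the 6 observed classes (root included at 0 steps)
        assert est.detail["rho"] == pytest.approx(5 / 6)
        assert est.generations == pytest.approx((5 / 6) / 0.03)

    def test_multiplicity_doubling_invariance(self):
        net1, root, chars = star_network(4)
        rates = {name: 0.005 for name in chars.names}
        classes2 = [(v, 2 * m) for v, m in sorted(net1.observed.items())]
        net2 = build_mj_network(classes2, chars)
        r1 = rho_tmrca(net1, root, rates)
        r2 = rho_tmrca(net2, root, rates)
        assert r1.detail["rho"] == pytest.approx(r2.detail["rho"])

    def test_missing_root_rejected(self):
        net, root, chars = star_network(3)
        with pytest.raises(ValueError, match="root"):
            rho_tmrca(net, tuple(99.0 for _ in chars.names), {n: 0.01 for n in chars.names})


def two_tip_dataset(panel, loci, deltas):
    base = {l: 13.0 for l in loci}
    other = {l: 13.0 + d for l, d in zip(loci, deltas)}
    return dataset_from_alleles(panel, [base, other])


class TestMCMC:
    def test_posterior_matches_numerical_integration_n2(self, panel):
        """For n=2, the sampled height distribution must match the closed
        posterior: Exp(t; N) coalescent prior x SMM transition over 2t."""
        loci = ("DYS391", "DYS392", "DYS439")
        rates = {"DYS391": 0.003, "DYS392": 0.002, "DYS439": 0.005}
        deltas = (1, 0, 2)
        ds = two_tip_dataset(panel, loci, deltas)
        N = 1500.0
        cfg = MCMCConfig(
            n_samples=120_000, burn_in=2000, thinning=10, seed=9,
            priors=MCMCPriors(fix_n=N, fix_growth=0.0),
        )
        est, trace = coalescent_mcmc_tmrca(ds, rates, cfg, loci=loci)
        h = trace["height"].to_numpy()[cfg.burn_in // cfg.thinning :]

        t = np.linspace(1.0, 30_000.0, 8000)
        logpost = -t / N
        for mu, d in zip(rates.values(), deltas):
            theta = 2 * mu * t
            logpost += np.log(ive(d, theta) + 1e-300)
        post = np.exp(logpost - logpost.max())
        cdf = np.cumsum(post)
        cdf /= cdf[-1]
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            sample_q = np.quantile(h, q)
            f_at_q = np.interp(sample_q, t, cdf)
            assert abs(f_at_q - q) < 0.05

    def test_identical_pair_pulls_posterior_below_prior(self, panel):
        loci = ("DYS391", "DYS392")
        rates = {"DYS391": 0.002, "DYS392": 0.002}
        ds = two_tip_dataset(panel, loci, (0, 0))
        N = 2000.0
        post_cfg = MCMCConfig(
            n_samples=60_000, burn_in=1000, thinning=10, seed=4,
            priors=MCMCPriors(fix_n=N, fix_growth=0.0),
        )
        est, _ = coalescent_mcmc_tmrca(ds, rates, post_cfg, loci=loci)
        prior_median = N * np.log(2)  # Exp(N) median for two lineages
        assert est.generations < prior_median

    def test_deterministic_given_seed(self, panel, slow_rates):
        from ypopgen import default_config, simulate_dataset

        ds, _, _ = simulate_dataset(default_config(seed=21, scale=0.004))
        sub = ds.subset(population="Han")
        cfg = MCMCConfig.scaled_down(seed=77, priors=MCMCPriors(fix_growth=0.0))
        e1, t1 = coalescent_mcmc_tmrca(sub, slow_rates, cfg)
        e2, t2 = coalescent_mcmc_tmrca(sub, slow_rates, cfg)
        assert e1.generations == e2.generations
        assert (t1["height"] == t2["height"]).all()

    def test_rejects_fractional_alleles(self, panel, slow_rates):
        ds = dataset_from_alleles(panel, [{"DYS391": 11.2}, {"DYS391": 12}])
        with pytest.raises(ValueError, match="integer"):
            coalescent_mcmc_tmrca(ds, slow_rates, MCMCConfig.scaled_down(seed=0), loci=("DYS391",))
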