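"""Time to the most recent common ancestor from Y-STR data.

Three estimators are provided:

* ``asd_tmrca`` — average squared distance from a founder haplotype; under
  the stepwise mutation model E[ASD_l] = mu_l * t, so the per-locus mean of
  ASD_l / mu_l estimates the age of a star-like genealogy.  Uncertainty by
  bootstrap over samples.
* ``rho_tmrca`` — mean mutational steps from a root node of a haplotype
  network; age = rho / sum_l mu_l generations, sigma_rho = sqrt(rho / n).
* ``coalescent_mcmc_tmrca`` — a single-population Bayesian coalescent
  sampler with exponential growth and an SMM likelihood (see _mcmc_core),
  reporting the posterior median tree height and central 95% interval.

Years are generations times the configured generation time (default 25).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .dataset import PopulationDataset, YHaplotype
from .network import HaplotypeNetwork, Vector

GENERATION_TIME_YEARS = 25.0


@dataclass(frozen=True)
class TMRCAEstimate:
    generations: float
    years: float
    interval_generations: tuple[float, float]
    interval_years: tuple[float, float]
    method: str
    generation_time: float
    detail: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        d["detail"] = {k: v for k, v in self.detail.items() if not isinstance(v, pd.DataFrame)}
        return json.dumps(d, default=float, indent=2)


def _make_estimate(
    gens: float, low: float, high: float, method: str,
    generation_time: float, detail: dict | None = None,
) -> TMRCAEstimate:
    return TMRCAEstimate(
        generations=float(gens),
        years=float(gens) * generation_time,
        interval_generations=(float(low), float(high)),
        interval_years=(float(low) * generation_time, float(high) * generation_time),
        method=method,
        generation_time=generation_time,
        detail=detail or {},
    )


def modal_haplotype(ds: PopulationDataset, loci: Sequence[str]) -> YHaplotype:
    """Component-wise most frequent allele; ties break to the smaller allele."""
    if not ds.samples:
        raise ValueError("empty dataset")
    alleles: dict[str, tuple[float, ...] | None] = {}
    for loc in loci:
        counts: dict[float, int] = {}
        for s in ds.samples:
            v = s.haplotype.single_value(loc)
            if v is not None:
                counts[v] = counts.get(v, 0) + 1
        if not counts:
            raise ValueError(f"all samples missing locus {loc}")
        best = min(counts, key=lambda a: (-counts[a], a))
        alleles[loc] = (best,)
    return YHaplotype(alleles=alleles)


def asd_tmrca(
    ds: PopulationDataset,
    rates: Mapping[str, float],
    loci: Sequence[str] | None = None,
    founder: YHaplotype | None = None,
    generation_time: float = GENERATION_TIME_YEARS,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> TMRCAEstimate:
    """ASD estimator: T = mean over loci of ASD_l / mu_l.

    ``loci`` defaults to the panel's 14-locus slow set; the founder defaults
    to the modal haplotype of the subset.
    """
    loci = tuple(loci) if loci is not None else ds.panel.slow
    if not loci:
        raise ValueError("no loci given")
    founder = founder or modal_haplotype(ds, loci)
    mat, _ = ds.allele_matrix(loci)
    if mat.shape[0] == 0:
        raise ValueError("no complete samples")
    f = np.array([founder.single_value(l) for l in loci], dtype=float)
    mus = np.array([rates[l] for l in loci], dtype=float)
    sq = (mat - f) ** 2
    t_hat = float(np.mean(sq.mean(axis=0) / mus))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    n = mat.shape[0]
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        boots[b] = np.mean(sq[idx].mean(axis=0) / mus)
    low, high = np.percentile(boots, [2.5, 97.5])
    return _make_estimate(
        t_hat, low, high, "asd", generation_time,
        detail={"n": n, "loci": list(loci), "n_bootstrap": n_bootstrap},
    )


def rho_tmrca(
    net: HaplotypeNetwork,
    root: Vector,
    rates: Mapping[str, float],
    generation_time: float = GENERATION_TIME_YEARS,
) -> TMRCAEstimate:
    """Rho estimator on a haplotype network.

    rho is the multiplicity-weighted mean of minimal mutational step counts
    from the root node to each observed class; T = rho / sum(mu).
    """
    root = tuple(float(x) for x in root)
    if root not in net.graph:
        raise ValueError("root is not a node of the network")
    steps = nx.single_source_dijkstra_path_length(net.graph, root, weight="steps")
    total_mult = sum(net.observed.values())
    rho = sum(net.observed[v] * steps[v] for v in net.observed) / total_mult
    str_loci = [n for n, snp in zip(net.chars.names, net.chars.is_snp) if not snp]
    mu_total = sum(rates[l] for l in str_loci)
    t_hat = rho / mu_total
    sigma_rho = np.sqrt(rho / total_mult)
    low = max(0.0, (rho - 1.96 * sigma_rho) / mu_total)
    high = (rho + 1.96 * sigma_rho) / mu_total
    return _make_estimate(
        t_hat, low, high, "rho", generation_time,
        detail={"rho": rho, "sigma_rho": float(sigma_rho), "mu_total": mu_total,
                "n": total_mult},
    )


# ---------------------------------------------------------------------------
# Bayesian coalescent MCMC


@dataclass
class MCMCPriors:
    """Priors of the single-population growth model (all configurable).

    Effective size is lognormal with the given median; scaled growth
    beta = alpha*N has an exponential prior with the given scale.  Setting
    ``fix_n``/``fix_growth`` replaces a prior by a point mass.
    """

    n_median: float = 1000.0
    log_n_sigma: float = 1.0
    growth_scale: float = 1.0
    fix_n: float | None = None
    fix_growth: float | None = None


@dataclass
class MCMCConfig:
    n_samples: int = 2_000_000  # production mirrors the study protocol
    burn_in: int = 3000
    thinning: int = 100
    seed: int = 0
    priors: MCMCPriors = field(default_factory=MCMCPriors)
    prior_only: bool = False
    lattice_pad: int = 10

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_samples:
            raise ValueError("burn_in must be smaller than n_samples")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @classmethod
    def scaled_down(cls, seed: int = 0, **kw) -> "MCMCConfig":
        """Short test preset (10,000 samples, 500 burn-in)."""
        kw.setdefault("n_samples", 10_000)
        kw.setdefault("burn_in", 500)
        kw.setdefault("thinning", 10)
        return cls(seed=seed, **kw)

    def digest(self) -> str:
        raw = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(raw.encode()).hexdigest()[:12]


def _initial_tree(mat: np.ndarray, mu_total: float) -> tuple[np.ndarray, ...]:
    """UPGMA starting genealogy from pairwise L1 allele distances."""
    n = mat.shape[0]
    m = 2 * n - 1
    parent = np.full(m, -1, dtype=np.int64)
    left = np.full(m, -1, dtype=np.int64)
    right = np.full(m, -1, dtype=np.int64)
    times = np.zeros(m)
    if n == 2:
        parent[0] = parent[1] = 2
        left[2], right[2] = 0, 1
        d = np.abs(mat[0] - mat[1]).sum()
        times[2] = max(1.0, d / max(mu_total, 1e-9) / 2.0)
        return parent, left, right, times
    z = linkage(pdist(mat, metric="cityblock"), method="average")
    t_prev = 0.0
    for k in range(n - 1):
        a, b, h, _ = z[k]
        u = n + k
        left[u], right[u] = int(a), int(b)
        parent[int(a)] = parent[int(b)] = u
        t = h / max(mu_total, 1e-9) / 2.0
        t = max(t, t_prev + 1.0)  # strictly increasing event times
        times[u] = t
        t_prev = t
    return parent, left, right, times


def coalescent_mcmc_tmrca(
    ds: PopulationDataset,
    rates: Mapping[str, float],
    cfg: MCMCConfig,
    loci: Sequence[str] | None = None,
    generation_time: float = GENERATION_TIME_YEARS,
) -> tuple[TMRCAEstimate, pd.DataFrame]:
    """Posterior TMRCA of a sample under the coalescent + SMM model.

    Returns the estimate (posterior median and central 95% interval of the
    genealogy height) and the thinned posterior trace.  Deterministic given
    ``cfg.seed``.  A split-half discrepancy in sampled heights beyond 25%
    sets ``detail["convergence_warning"]``.
    """
    from ._mcmc_core import run_mcmc

    loci = tuple(loci) if loci is not None else ds.panel.slow
    mat, _ = ds.allele_matrix(loci)
    if mat.shape[0] < 2:
        raise ValueError("need at least two complete samples")
    if not np.allclose(mat, np.round(mat)):
        raise ValueError("SMM likelihood requires integer repeat counts")
    mat = np.round(mat).astype(np.int64)
    mus = np.array([rates[l] for l in loci], dtype=float)
    pad = cfg.lattice_pad
    offsets = mat.min(axis=0) - pad
    sizes = (mat.max(axis=0) - mat.min(axis=0) + 2 * pad + 1).astype(np.int64)
    states = (mat - offsets).astype(np.int64)

    priors = cfg.priors
    n_init = priors.fix_n if priors.fix_n is not None else priors.n_median
    beta_init = priors.fix_growth if priors.fix_growth is not None else 0.1
    parent, leftc, rightc, times = _initial_tree(mat.astype(float), float(mus.sum()))

    heights, logliks, ns, betas, n_acc, n_prop = run_mcmc(
        states, mus, sizes, parent, leftc, rightc, times,
        int(cfg.n_samples), int(cfg.thinning), int(cfg.seed) & 0x7FFFFFFF,
        int(cfg.prior_only),
        float(n_init), int(priors.fix_n is not None),
        float(np.log(priors.n_median)), float(priors.log_n_sigma),
        float(beta_init), int(priors.fix_growth is not None),
        float(priors.growth_scale),
    )
    keep = slice(cfg.burn_in // cfg.thinning, None)
    h = heights[keep]
    trace = pd.DataFrame(
        {
            "iteration": (np.arange(len(heights)) + 1) * cfg.thinning,
            "height": heights,
            "loglik": logliks,
            "N": ns,
            "beta": betas,
        }
    )
    med = float(np.median(h))
    low, high = np.percentile(h, [2.5, 97.5])
    half = len(h) // 2
    m1, m2 = np.median(h[:half]), np.median(h[half:])
    converged = abs(m1 - m2) <= 0.25 * max(med, 1e-9)
    if not converged:
        warnings.warn("MCMC split-half height medians differ by >25%; inspect the trace")
    est = _make_estimate(
        med, low, high, "mcmc", generation_time,
        detail={
            "n": int(mat.shape[0]),
            "acceptance_rate": float(n_acc) / max(n_prop, 1),
            "config_digest": cfg.digest(),
            "convergence_warning": not converged,
        },
    )
    return est, trace
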