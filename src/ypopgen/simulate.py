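"""Coalescent synthetic-data generator for Y-haplotype pipelines.

Emulates the statistical structure the analyses assume: per-group coalescent
genealogies (with optional exponential growth), stepwise STR mutation with
per-locus rates, single-origin haplogroup-defining SNPs, and multi-population
mixtures.  The default configuration mirrors the five-ethnicity study design:
population sizes 1266/654/680/427/314 and haplogroup mixtures anchored on
the published frequency table (Han O 0.800, Kyrgyz R 0.455, ...).

Randomness discipline: everything derives from one integer seed through
named `numpy` SeedSequence substreams — one per population x haplogroup
cluster, one per haplogroup founder — so datasets are byte-identical across
runs for the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dataset import LocusCall, PopulationDataset, SampleRecord, YHaplotype
from .haplogroups import HaplogroupTree, default_tree, parse_haplogroup_name
from .panel import LocusPanel, default_panel


@dataclass
class SimTree:
    """Array-encoded rooted binary genealogy (tips 0..n-1 at time 0)."""

    parent: np.ndarray
    left: np.ndarray
    right: np.ndarray
    times: np.ndarray  # generations before present
    n: int

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def tmrca(self) -> float:
        return float(self.times[self.root])


def simulate_tree(
    n: int, N: float, growth: float = 0.0, seed: int | np.random.Generator = 0
) -> SimTree:
    """Haploid coalescent genealogy with exponential growth.

    Backwards in time the population size is N*exp(-growth*t), so with
    ``growth`` = 0 the waiting time with k lineages is Exp(k(k-1)/(2N)) and
    E[TMRCA] = 2N(1 - 1/n).
    """
    if n < 2:
        raise ValueError("need at least two tips")
    if N <= 0:
        raise ValueError("effective size must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = 2 * n - 1
    parent = np.full(m, -1, dtype=np.int64)
    left = np.full(m, -1, dtype=np.int64)
    right = np.full(m, -1, dtype=np.int64)
    times = np.zeros(m)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        pairs = k * (k - 1) / 2.0
        u = rng.exponential(1.0)
        if growth > 1e-12:
            t = np.log(np.exp(growth * t) + u * growth * N / pairs) / growth
        else:
            t = t + u * N / pairs
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        left[nxt], right[nxt] = a, b
        times[nxt] = t
        active[i] = nxt
        del active[j]
        nxt += 1
    return SimTree(parent=parent, left=left, right=right, times=times, n=n)


def star_tree(n: int, depth: float) -> SimTree:
    """Degenerate star genealogy: all tips coalesce at ``depth`` generations.

    Encoded as a caterpillar with all internal nodes at (numerically
    indistinguishable) depth, so every tip sits on a branch of length
    ``depth`` from the common ancestor.
    """
    m = 2 * n - 1
    parent = np.full(m, -1, dtype=np.int64)
    left = np.full(m, -1, dtype=np.int64)
    right = np.full(m, -1, dtype=np.int64)
    times = np.zeros(m)
    cur = 0
    for k in range(n - 1):
        u = n + k
        left[u], right[u] = cur, k + 1
        parent[cur] = parent[k + 1] = u
        times[u] = depth  # zero-length internal edges: star shape
        cur = u
    return SimTree(parent=parent, left=left, right=right, times=times, n=n)


def mutate_str(
    tree: SimTree,
    founder: Mapping[str, float],
    rates: Mapping[str, float],
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Drop SMM mutations on a genealogy; returns locus -> tip allele array.

    On each branch of length t, per locus, the mutation count is
    Poisson(mu*t) and each mutation steps +-1 repeat with probability 1/2.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    missing = [l for l in founder if l not in rates]
    if missing:
        raise ValueError(f"rates missing for loci: {missing}")
    m = tree.parent.shape[0]
    out: dict[str, np.ndarray] = {}
    # root first; ties (zero-length internal edges) broken parent-before-child
    order = sorted(range(m), key=lambda u: (-tree.times[u], -u))
    for loc in founder:
        mu = rates[loc]
        state = np.zeros(m)
        state[tree.root] = founder[loc]
        for u in order:
            for c in (tree.left[u], tree.right[u]):
                if c < 0:
                    continue
                t = tree.times[u] - tree.times[c]
                k = rng.poisson(mu * t)
                step = 0.0
                if k:
                    step = 2.0 * rng.binomial(k, 0.5) - k
                state[c] = state[u] + step
        out[loc] = state[: tree.n].copy()
    return out


# ---------------------------------------------------------------------------
# Full-dataset simulation


# Population mixtures reconstructed from the five-ethnicity frequency table
# (major-clade level; renormalised).  Sizes are the reciprocals of each
# population's minimum haplotype frequency.
DEFAULT_MIXTURES: dict[str, dict[str, float]] = {
    "Han": {"C": 0.083, "D": 0.013, "E": 0.002, "J": 0.001, "L": 0.004,
            "N": 0.062, "O": 0.800, "Q": 0.026, "R": 0.010},
    "Hui": {"C": 0.083, "D": 0.012, "E": 0.026, "F": 0.005, "G": 0.015,
            "H": 0.023, "I": 0.011, "J": 0.097, "L": 0.020, "N": 0.075,
            "O": 0.474, "Q": 0.040, "R": 0.118},
    "Mongolia": {"C": 0.346, "D": 0.009, "E": 0.041, "G": 0.007, "I": 0.006,
                 "J": 0.018, "L": 0.001, "N": 0.115, "O": 0.365, "Q": 0.027,
                 "R": 0.065},
    "Yi": {"C": 0.037, "D": 0.244, "F": 0.049, "N": 0.077, "O": 0.583,
           "Q": 0.009},
    "Kyrgyz": {"C": 0.347, "D": 0.048, "E": 0.006, "G": 0.006, "H": 0.003,
               "J": 0.067, "L": 0.013, "T": 0.006, "N": 0.035, "Q": 0.013,
               "R": 0.455},
}

DEFAULT_SIZES = {"Han": 1266, "Hui": 654, "Mongolia": 680, "Yi": 427, "Kyrgyz": 314}

DEFAULT_COORDS = {
    "Han": (34.0, 113.0),
    "Hui": (36.5, 103.5),
    "Mongolia": (44.0, 112.0),
    "Yi": (27.5, 102.5),
    "Kyrgyz": (41.5, 75.5),
}

# Typical modal repeat counts used as the base founder haplotype.
DEFAULT_FOUNDER: dict[str, float] = {
    "DYS19": 15, "DYS389I": 13, "DYS389b": 16, "DYS390": 24, "DYS391": 10,
    "DYS392": 13, "DYS393": 13, "DYS437": 14, "DYS438": 10, "DYS439": 12,
    "DYS448": 19, "DYS449": 30, "DYS456": 15, "DYS458": 17, "DYS460": 11,
    "DYS481": 23, "DYS518": 38, "DYS533": 11, "DYS570": 17, "DYS576": 18,
    "DYS627": 21, "DYS635": 21, "YGATAH4": 12,
    "DYS385#1": 13, "DYS385#2": 16, "DYF387S1#1": 36, "DYF387S1#2": 38,
}


@dataclass
class PopulationConfig:
    label: str
    size: int
    latitude: float
    longitude: float
    mixture: dict[str, float]  # haplogroup (tree node) -> weight, sums to 1

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("population size must be >= 1")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            self.mixture = {k: v / total for k, v in self.mixture.items()}


@dataclass
class SimConfig:
    populations: list[PopulationConfig]
    panel: LocusPanel = field(default_factory=default_panel)
    tree: HaplogroupTree = field(default_factory=default_tree)
    effective_size: float = 1000.0
    growth: float = 0.0
    founder: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FOUNDER))
    founder_divergence: float = 2.5  # sd (repeats) of per-haplogroup founder offsets
    seed: int = 0


def default_config(seed: int = 0, scale: float = 1.0) -> SimConfig:
    """Study-calibrated configuration; ``scale`` shrinks sample sizes."""
    pops = [
        PopulationConfig(
            label=p,
            size=max(2, int(round(DEFAULT_SIZES[p] * scale))),
            latitude=DEFAULT_COORDS[p][0],
            longitude=DEFAULT_COORDS[p][1],
            mixture=dict(DEFAULT_MIXTURES[p]),
        )
        for p in DEFAULT_SIZES
    ]
    return SimConfig(populations=pops, seed=seed)


def _sim_loci(panel: LocusPanel) -> list[str]:
    """Per-lineage simulation loci: multi-copy loci split into sub-lineages."""
    out = []
    for loc in panel.loci:
        if loc.copy_number == 1:
            out.append(loc.name)
        else:
            out.extend(f"{loc.name}#{i+1}" for i in range(loc.copy_number))
    return out


def _sim_rates(panel: LocusPanel) -> dict[str, float]:
    rates = {}
    for loc in panel.loci:
        if loc.copy_number == 1:
            rates[loc.name] = loc.mutation_rate
        else:
            for i in range(loc.copy_number):
                rates[f"{loc.name}#{i+1}"] = loc.mutation_rate
    return rates


def _terminal_clades(tree: HaplogroupTree, trunk: str) -> list[str]:
    """Leaf clades of the nomenclature tree under a trunk (or the trunk itself)."""
    if trunk not in tree.nodes:
        raise ValueError(f"mixture names haplogroup {trunk!r} absent from the tree")
    leaves = [n for n in tree.members(trunk) if not tree.children(n)]
    return leaves or [trunk]


def _clade_name(tree: HaplogroupTree, clade: str) -> str:
    snp = tree.defining_snp(clade)
    return f"{clade}-{snp}" if snp else clade


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[PopulationDataset, dict, dict[str, dict[str, str]]]:
    """Simulate a multi-population Y-haplotype dataset.

    Returns (dataset, truth record, SNP states).  The truth record carries,
    per population x terminal clade cluster, the simulated TMRCA, founder
    haplotype and sample count, plus the generating parameters.  SNP states
    map sample_id -> {snp: "D"|"A"} consistently with clade membership.
    """
    panel = cfg.panel
    sim_loci = _sim_loci(panel)
    sim_rates = _sim_rates(panel)
    for l in sim_loci:
        if l not in cfg.founder:
            raise ValueError(f"founder haplotype missing locus {l}")

    # deterministic founder offsets per terminal clade
    all_terminals = sorted(
        {t for pop in cfg.populations for hg in pop.mixture for t in _terminal_clades(cfg.tree, hg)}
    )
    founders: dict[str, dict[str, float]] = {}
    for hi, clade in enumerate(all_terminals):
        frng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1, hi)))
        founders[clade] = {
            l: cfg.founder[l] + round(float(frng.normal(0.0, cfg.founder_divergence)))
            for l in sim_loci
        }

    snp_by_clade: dict[str, dict[str, str]] = {}
    for clade in all_terminals:
        on_path = set(cfg.tree.ancestors(clade))
        snp_by_clade[clade] = {
            snp: ("D" if node in on_path else "A")
            for node, (_, snp) in cfg.tree.nodes.items()
            if snp
        }

    samples: list[SampleRecord] = []
    snp_states: dict[str, dict[str, str]] = {}
    truth: dict = {
        "seed": cfg.seed,
        "effective_size": cfg.effective_size,
        "growth": cfg.growth,
        "clusters": [],
    }
    for pi, pop in enumerate(sorted(cfg.populations, key=lambda p: p.label)):
        prng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(2, pi)))
        trunks = sorted(pop.mixture)
        counts = prng.multinomial(pop.size, [pop.mixture[t] for t in trunks])
        sample_no = 0
        for trunk, n_trunk in zip(trunks, counts):
            if n_trunk == 0:
                continue
            terminals = _terminal_clades(cfg.tree, trunk)
            sub_counts = prng.multinomial(n_trunk, [1.0 / len(terminals)] * len(terminals))
            for clade, n_cl in zip(terminals, sub_counts):
                if n_cl == 0:
                    continue
                hi = all_terminals.index(clade)
                crng = np.random.default_rng(
                    np.random.SeedSequence(entropy=cfg.seed, spawn_key=(3, pi, hi))
                )
                founder = founders[clade]
                if n_cl >= 2:
                    tree = simulate_tree(n_cl, cfg.effective_size, cfg.growth, crng)
                    tips = mutate_str(tree, founder, sim_rates, crng)
                    tmrca = tree.tmrca
                else:
                    # a single lineage: private drift over an exponential time
                    t = float(crng.exponential(cfg.effective_size))
                    single = star_tree(2, t)
                    tips_all = mutate_str(single, founder, sim_rates, crng)
                    tips = {l: v[:1] for l, v in tips_all.items()}
                    tmrca = 0.0
                for i in range(n_cl):
                    sample_no += 1
                    sid = f"{pop.label}_{sample_no:05d}"
                    alleles: dict[str, LocusCall | None] = {}
                    for loc in panel.loci:
                        if loc.copy_number == 1:
                            v = tips[loc.name][i]
                            alleles[loc.name] = (float(np.clip(v, 5, 60)),)
                        else:
                            vs = [
                                float(np.clip(tips[f"{loc.name}#{j+1}"][i], 5, 60))
                                for j in range(loc.copy_number)
                            ]
                            alleles[loc.name] = tuple(sorted(vs))
                    samples.append(
                        SampleRecord(
                            sample_id=sid,
                            population=pop.label,
                            ethnicity=pop.label,
                            latitude=pop.latitude,
                            longitude=pop.longitude,
                            haplogroup=_clade_name(cfg.tree, clade),
                            haplotype=YHaplotype(alleles=alleles),
                        )
                    )
                    snp_states[sid] = dict(snp_by_clade[clade])
                truth["clusters"].append(
                    {
                        "population": pop.label,
                        "haplogroup": clade,
                        "n": int(n_cl),
                        "tmrca_generations": float(tmrca),
                        "founder": {l: founder[l] for l in sim_loci},
                    }
                )
    ds = PopulationDataset(panel=panel, samples=samples)
    return ds, truth, snp_states
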