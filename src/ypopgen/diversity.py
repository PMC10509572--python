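"""Forensic frequency and diversity statistics for Y-haplotype data.

All statistics derive from a frequency spectrum obtained by direct counting:
gene/haplotype/haplogroup diversity n(1 - sum pi^2)/(n - 1), discrimination
capacity (observed haplotypes / sample size) and match probability
(sum pi^2).  Samples missing data for the chosen key are excluded from that
statistic only; the exclusion count is recorded on the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import pandas as pd

from .dataset import PopulationDataset
from .haplogroups import collapse_to_level, parse_haplogroup_name




def _group_labels(ds, by: str):
    if by == "population":
        return ds.populations
    if by == "ethnicity":
        return ds.ethnicities
    raise ValueError("by must be 'population' or 'ethnicity'")


class EmptySpectrumError(ValueError):
    pass


class UndefinedStatisticError(ValueError):
    pass


@dataclass(frozen=True)
class FrequencySpectrum:
    """Category counts for one categoriser (haplogroup, allele or haplotype)."""

    categories: dict[Hashable, int]
    kind: str  # "haplogroup" | "allele" | "haplotype" | "gene"
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not self.categories:
            raise EmptySpectrumError("no samples left after missing-data exclusion")
        if any(c < 1 for c in self.categories.values()):
            raise ValueError("category counts must be >= 1")

    @property
    def n(self) -> int:
        return sum(self.categories.values())

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def frequencies(self) -> dict[Hashable, float]:
        n = self.n
        return {k: c / n for k, c in self.categories.items()}

    @property
    def sum_pi_sq(self) -> float:
        n = self.n
        return sum((c / n) ** 2 for c in self.categories.values())


def spectrum_from_values(values: Sequence[Hashable], kind: str, n_excluded: int = 0) -> FrequencySpectrum:
    counts: dict[Hashable, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return FrequencySpectrum(categories=counts, kind=kind, n_excluded=n_excluded)


def frequency_spectrum(
    ds: PopulationDataset,
    key: str = "haplotype",
    level: int | None = None,
    locus: str | None = None,
) -> FrequencySpectrum:
    """Direct-counting spectrum for one of the three categorisers.

    key="haplogroup" counts haplogroup calls, collapsed to ``level``
    refinements when given (None keeps terminal calls); key="allele" counts
    locus calls at ``locus`` (multi-copy combinations are one category);
    key="haplotype" counts whole-panel haplotype identities.
    """
    if key == "haplogroup":
        values, excluded = [], 0
        for s in ds.samples:
            name = parse_haplogroup_name(s.haplogroup)
            if level is not None:
                name = collapse_to_level(name, level)
                values.append(name.bare())
            else:
                values.append(name.render())
        return spectrum_from_values(values, "haplogroup", excluded)
    if key == "allele":
        if locus is None:
            raise ValueError("allele spectrum requires a locus")
        calls = [s.haplotype.alleles.get(locus) for s in ds.samples]
        kept = [c for c in calls if c is not None]
        return spectrum_from_values(kept, "allele", n_excluded=len(calls) - len(kept))
    if key == "haplotype":
        loci = ds.panel.locus_names
        idents = ds.haplotype_identities(loci)
        kept = [h for h in idents if all(c is not None for c in h)]
        return spectrum_from_values(kept, "haplotype", n_excluded=len(idents) - len(kept))
    raise ValueError(f"unknown categoriser {key!r}")


@dataclass(frozen=True)
class DiversityResult:
    value: float
    n: int
    sum_pi_sq: float
    kind: str


def diversity(spec: FrequencySpectrum) -> DiversityResult:
    """Unbiased diversity n(1 - sum pi^2)/(n - 1); undefined for n < 2."""
    n = spec.n
    if n < 2:
        raise UndefinedStatisticError("diversity requires n >= 2")
    value = n * (1.0 - spec.sum_pi_sq) / (n - 1)
    return DiversityResult(value=value, n=n, sum_pi_sq=spec.sum_pi_sq, kind=spec.kind)


def discrimination_capacity(spec: FrequencySpectrum) -> float:
    """Observed haplotypes / total samples; haplotype spectra only."""
    if spec.kind != "haplotype":
        raise ValueError("discrimination capacity is defined on haplotype spectra")
    return spec.n_categories / spec.n


def match_probability(spec: FrequencySpectrum) -> float:
    """Probability that two random males share a category (sum pi^2)."""
    return spec.sum_pi_sq


def per_locus_gene_diversity(ds: PopulationDataset) -> pd.DataFrame:
    """Gene diversity per panel locus; multi-copy combinations are one unit.

    Returns a frame (locus, gd, n, n_alleles) ordered as the panel.
    """
    rows = []
    for loc in ds.panel.locus_names:
        spec = frequency_spectrum(ds, key="allele", locus=loc)
        res = diversity(spec)
        rows.append({"locus": loc, "gd": res.value, "n": res.n, "n_alleles": spec.n_categories})
    return pd.DataFrame(rows)


def population_summary(ds: PopulationDataset, by: str = "population") -> pd.DataFrame:
    """HD, DC, MP and haplogroup diversity per group (and pooled "all")."""
    groups = list(_group_labels(ds, by)) if by in ("population", "ethnicity") else None
    if groups is None:
        raise ValueError("by must be 'population' or 'ethnicity'")
    rows = []
    for label in groups + ["all"]:
        sub = ds if label == "all" else ds.subset(**{by: label})
        hap = frequency_spectrum(sub, key="haplotype")
        hg = frequency_spectrum(sub, key="haplogroup")
        rows.append(
            {
                by: label,
                "n": hap.n,
                "n_haplotypes": hap.n_categories,
                "haplotype_diversity": diversity(hap).value,
                "discrimination_capacity": discrimination_capacity(hap),
                "match_probability": match_probability(hap),
                "haplogroup_diversity": diversity(hg).value,
            }
        )
    return pd.DataFrame(rows)


def haplogroup_frequency_table(ds: PopulationDataset, level: int = 0, by: str = "ethnicity") -> pd.DataFrame:
    """Per-group haplogroup frequency matrix at a collapse level (rows sum to 1)."""
    groups = list(_group_labels(ds, by))
    rows = {}
    for label in ["all"] + groups:
        sub = ds if label == "all" else ds.subset(**{by: label})
        spec = frequency_spectrum(sub, key="haplogroup", level=level)
        rows[label] = spec.frequencies()
    table = pd.DataFrame(rows).T.fillna(0.0)
    return table[sorted(table.columns)]
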