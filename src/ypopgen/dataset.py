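"""In-memory containers for Y-haplotype datasets.

An allele is a repeat count stored as a float (intermediate alleles such as
17.2 are valid); a locus call is an unordered multiset of alleles of size
equal to the locus copy number, stored as a sorted tuple, or ``None`` when
missing.  Haplotype identity (used for counting distinct haplotypes) is the
tuple of locus calls over all panel loci, so multi-copy combinations compare
order-invariantly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import LocusPanel, default_panel

ALLELE_MIN = 5.0
ALLELE_MAX = 60.0
_VALID_FRACTIONS = (0.0, 0.1, 0.2, 0.3)

LocusCall = tuple[float, ...]  # sorted allele multiset; None means missing


class AlleleError(ValueError):
    """Raised for allele values outside forensic reporting conventions."""


def check_allele(value: float) -> float:
    """Validate a single repeat count (range and fractional part)."""
    v = float(value)
    if not (ALLELE_MIN <= v <= ALLELE_MAX):
        raise AlleleError(f"allele {value!r} outside [{ALLELE_MIN:g}, {ALLELE_MAX:g}]")
    frac = round(v - int(v), 6)
    if not any(abs(frac - f) < 1e-6 for f in _VALID_FRACTIONS):
        raise AlleleError(f"allele {value!r} has invalid fractional part")
    return v


def locus_call(values: Iterable[float]) -> LocusCall:
    """Build an order-invariant locus call from raw allele values."""
    return tuple(sorted(check_allele(v) for v in values))


@dataclass(frozen=True)
class YHaplotype:
    """Map of locus name -> locus call (sorted tuple) or None for missing."""

    alleles: Mapping[str, LocusCall | None]

    def __getitem__(self, locus: str) -> LocusCall | None:
        return self.alleles[locus]

    def identity(self, loci: Sequence[str]) -> tuple:
        """Hashable haplotype identity over the given loci."""
        return tuple(self.alleles.get(l) for l in loci)

    def single_value(self, locus: str) -> float | None:
        call = self.alleles.get(locus)
        if call is None:
            return None
        if len(call) != 1:
            raise ValueError(f"{locus} is not single-copy")
        return call[0]

    def is_complete(self, loci: Sequence[str]) -> bool:
        return all(self.alleles.get(l) is not None for l in loci)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    population: str
    ethnicity: str
    latitude: float
    longitude: float
    haplogroup: str
    haplotype: YHaplotype


@dataclass
class PopulationDataset:
    """A panel plus a collection of per-male sample records."""

    panel: LocusPanel
    samples: list[SampleRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.samples)

    @property
    def populations(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.population, None)
        return tuple(seen)

    @property
    def ethnicities(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.ethnicity, None)
        return tuple(seen)

    def subset(
        self,
        population: str | None = None,
        ethnicity: str | None = None,
        haplogroup_prefix: str | None = None,
    ) -> "PopulationDataset":
        """Select samples by population, ethnicity, and/or haplogroup clade.

        ``haplogroup_prefix`` selects terminal calls belonging to the named
        clade by nomenclature prefix (e.g. "C2a" matches "C2a1a3-M504").
        """
        kept = []
        for s in self.samples:
            if population is not None and s.population != population:
                continue
            if ethnicity is not None and s.ethnicity != ethnicity:
                continue
            if haplogroup_prefix is not None:
                name = s.haplogroup.split("-")[0].rstrip("*")
                if not name.startswith(haplogroup_prefix):
                    continue
            kept.append(s)
        return PopulationDataset(panel=self.panel, samples=kept)

    def allele_matrix(
        self, loci: Sequence[str], drop_incomplete: bool = True
    ) -> tuple[np.ndarray, list[str]]:
        """Numeric allele matrix over single-copy loci.

        Returns (matrix n_samples x n_loci, sample_ids).  Samples missing any
        requested locus are dropped when ``drop_incomplete`` (default).
        """
        rows, ids = [], []
        for s in self.samples:
            vals = [s.haplotype.single_value(l) for l in loci]
            if drop_incomplete and any(v is None for v in vals):
                continue
            rows.append([np.nan if v is None else v for v in vals])
            ids.append(s.sample_id)
        return np.asarray(rows, dtype=float).reshape(len(rows), len(loci)), ids

    def haplotype_identities(self, loci: Sequence[str] | None = None) -> list[tuple]:
        loci = self.panel.locus_names if loci is None else tuple(loci)
        return [s.haplotype.identity(loci) for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with one column per locus, multi-copy joined by '-'."""
        from .io import format_locus_call  # local import to avoid cycle

        records = []
        for s in self.samples:
            row: dict[str, object] = {
                "sample_id": s.sample_id,
                "population": s.population,
                "ethnicity": s.ethnicity,
                "latitude": s.latitude,
                "longitude": s.longitude,
                "haplogroup": s.haplogroup,
            }
            for loc in self.panel.locus_names:
                row[loc] = format_locus_call(s.haplotype.alleles.get(loc))
            records.append(row)
        return pd.DataFrame(records)
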