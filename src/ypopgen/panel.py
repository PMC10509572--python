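"""Locus panel definitions for Y-STR haplotyping.

The default panel mirrors the 27-STR forensic kit layout used throughout the
package: 23 single-copy loci plus the two multi-copy loci DYS385 and DYF387S1
(each reported as an unordered two-allele combination), with DYS389b derived
as DYS389II - DYS389I.  Per-locus mutation rates are YHRD-style
per-generation defaults shipped with this package (artifact defaults, user
overridable via a panel TSV), and network weights 1-5 are assigned by rate
quintile (slowest bin -> 5, fastest bin -> 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: Y-SNP characters carry this weight in median-joining networks.
SNP_NETWORK_WEIGHT = 99

MULTI_COPY_LOCI = ("DYS385", "DYF387S1")

#: The 14 slowly-mutating loci used for TMRCA estimation.
SLOW_LOCI = (
    "DYS389I", "DYS389b", "DYS390", "DYS391", "DYS392", "DYS393",
    "DYS437", "DYS438", "DYS439", "DYS448", "DYS456", "DYS458",
    "DYS635", "YGATAH4",
)

# (name, copy_number, mutation_rate per generation).  Rates are artifact
# defaults in the range reported by YHRD for these markers.
_DEFAULT_PANEL_SPEC: tuple[tuple[str, int, float], ...] = (
    ("DYS19", 1, 0.0023),
    ("DYS389I", 1, 0.0025),
    ("DYS389b", 1, 0.0028),
    ("DYS390", 1, 0.0021),
    ("DYS391", 1, 0.0026),
    ("DYS392", 1, 0.0004),
    ("DYS393", 1, 0.0011),
    ("DYS437", 1, 0.0011),
    ("DYS438", 1, 0.0004),
    ("DYS439", 1, 0.0051),
    ("DYS448", 1, 0.0014),
    ("DYS449", 1, 0.0122),
    ("DYS456", 1, 0.0042),
    ("DYS458", 1, 0.0071),
    ("DYS460", 1, 0.0057),
    ("DYS481", 1, 0.0050),
    ("DYS518", 1, 0.0184),
    ("DYS533", 1, 0.0040),
    ("DYS570", 1, 0.0124),
    ("DYS576", 1, 0.0143),
    ("DYS627", 1, 0.0123),
    ("DYS635", 1, 0.0037),
    ("YGATAH4", 1, 0.0025),
    ("DYS385", 2, 0.0023),
    ("DYF387S1", 2, 0.0157),
)


@dataclass(frozen=True)
class LocusDescriptor:
    """One STR locus: identity, copy number, mutation rate, network weight.

    ``copy_number`` is 1 for ordinary loci and 2 for the combination loci
    DYS385 / DYF387S1.  ``is_single_copy`` marks membership in the 23-locus
    subset used for FST and network construction; ``is_slow`` marks the
    14-locus slowly-mutating subset used for dating.
    """

    name: str
    copy_number: int
    mutation_rate: float
    network_weight: int
    is_slow: bool
    is_single_copy: bool

    def __post_init__(self) -> None:
        if self.copy_number not in (1, 2):
            raise ValueError(f"{self.name}: copy_number must be 1 or 2")
        if not (0.0 < self.mutation_rate < 0.1):
            raise ValueError(f"{self.name}: mutation rate out of (0, 0.1)")
        if not (1 <= self.network_weight <= SNP_NETWORK_WEIGHT):
            raise ValueError(f"{self.name}: network weight out of [1, 99]")
        expected_single = self.copy_number == 1 and self.name not in MULTI_COPY_LOCI
        if self.is_single_copy != expected_single:
            raise ValueError(f"{self.name}: is_single_copy inconsistent with copy number")


def _quintile_weights(names: Sequence[str], rates: Sequence[float]) -> dict[str, int]:
    """Map loci to network weights 1-5 by mutation-rate quintile (slow -> 5)."""
    order = sorted(range(len(names)), key=lambda i: (rates[i], names[i]))
    n = len(names)
    weights: dict[str, int] = {}
    for rank, i in enumerate(order):
        quintile = min(4, rank * 5 // n)  # 0 = slowest bin
        weights[names[i]] = 5 - quintile
    return weights


@dataclass(frozen=True)
class LocusPanel:
    """Ordered collection of locus descriptors with named subsets."""

    loci: tuple[LocusDescriptor, ...]
    name: str = "YfilerPlus27"

    def __post_init__(self) -> None:
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names in panel")

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(loc.name for loc in self.loci)

    @property
    def n_str(self) -> int:
        """Total STR count weighted by copy number (27 for the default panel)."""
        return sum(loc.copy_number for loc in self.loci)

    def __getitem__(self, name: str) -> LocusDescriptor:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(loc.name == name for loc in self.loci)

    @property
    def single_copy(self) -> tuple[str, ...]:
        return tuple(loc.name for loc in self.loci if loc.is_single_copy)

    @property
    def slow(self) -> tuple[str, ...]:
        return tuple(loc.name for loc in self.loci if loc.is_slow)

    @property
    def multi_copy(self) -> tuple[str, ...]:
        return tuple(loc.name for loc in self.loci if loc.copy_number == 2)

    def mutation_rates(self, loci: Iterable[str] | None = None) -> dict[str, float]:
        names = self.locus_names if loci is None else tuple(loci)
        return {n: self[n].mutation_rate for n in names}

    def network_weights(self) -> dict[str, int]:
        return {loc.name: loc.network_weight for loc in self.loci}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": [l.name for l in self.loci],
                "copy_number": [l.copy_number for l in self.loci],
                "mutation_rate": [l.mutation_rate for l in self.loci],
                "network_weight": [l.network_weight for l in self.loci],
                "is_slow": [l.is_slow for l in self.loci],
                "is_single_copy": [l.is_single_copy for l in self.loci],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def default_panel() -> LocusPanel:
    """The 27-STR default panel (23 single-copy + DYS385 + DYF387S1)."""
    names = [n for n, _, _ in _DEFAULT_PANEL_SPEC]
    rates = [r for _, _, r in _DEFAULT_PANEL_SPEC]
    weights = _quintile_weights(names, rates)
    loci = tuple(
        LocusDescriptor(
            name=n,
            copy_number=c,
            mutation_rate=r,
            network_weight=weights[n],
            is_slow=n in SLOW_LOCI,
            is_single_copy=(c == 1 and n not in MULTI_COPY_LOCI),
        )
        for n, c, r in _DEFAULT_PANEL_SPEC
    )
    return LocusPanel(loci=loci)


def read_panel(path: str | Path) -> LocusPanel:
    """Read a locus panel from TSV (locus, copy_number, mutation_rate, ...)."""
    df = pd.read_csv(path, sep="\t")
    required = {"locus", "copy_number", "mutation_rate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel file missing columns: {sorted(missing)}")
    if "network_weight" not in df.columns:
        weights = _quintile_weights(df["locus"].tolist(), df["mutation_rate"].tolist())
        df["network_weight"] = [weights[n] for n in df["locus"]]
    if "is_slow" not in df.columns:
        df["is_slow"] = df["locus"].isin(SLOW_LOCI)
    if "is_single_copy" not in df.columns:
        df["is_single_copy"] = (df["copy_number"] == 1) & ~df["locus"].isin(MULTI_COPY_LOCI)
    loci = tuple(
        LocusDescriptor(
            name=str(r.locus),
            copy_number=int(r.copy_number),
            mutation_rate=float(r.mutation_rate),
            network_weight=int(r.network_weight),
            is_slow=bool(r.is_slow),
            is_single_copy=bool(r.is_single_copy),
        )
        for r in df.itertuples()
    )
    return LocusPanel(loci=loci, name=str(Path(path).stem))
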