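"""Reading, writing and validation of haplotype tables.

Tables are TSV/CSV with a header row: the mandatory metadata columns
(sample_id, population, ethnicity, latitude, longitude, haplogroup) followed
by one column per panel locus.  Multi-copy allele combinations are joined by
"-" ("11-14"); intermediate alleles use a decimal point ("17.2").  DYS389b is
derived from DYS389II - DYS389I when the table reports DYS389II.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .dataset import (
    AlleleError,
    LocusCall,
    PopulationDataset,
    SampleRecord,
    YHaplotype,
    check_allele,
    locus_call,
)
from .panel import LocusPanel, default_panel

META_COLUMNS = ("sample_id", "population", "ethnicity", "latitude", "longitude", "haplogroup")

_MISSING_TOKENS = {"", "na", "nan", "none", "-", "."}
_ALLELE_RE = re.compile(r"^\d{1,2}(\.\d)?$")


class FormatError(ValueError):
    """Table-level structural problem (missing column, bad header)."""


class RowError(ValueError):
    """Row-level problem; carries the 1-based data row number."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


def parse_allele_token(token: str) -> float | None:
    """Parse one allele token; returns None for a missing value.

    Accepts integers and one-decimal intermediates (e.g. "17.2"); anything
    else is a parse error.
    """
    tok = str(token).strip()
    if tok.lower() in _MISSING_TOKENS:
        return None
    # pandas may render integer alleles as "13.0"
    if tok.endswith(".0"):
        tok = tok[:-2]
    if not _ALLELE_RE.match(tok):
        raise AlleleError(f"unparseable allele token {token!r}")
    return check_allele(float(tok))


def parse_locus_token(token: str, copy_number: int) -> LocusCall | None:
    """Parse a locus cell: single allele, or "-"-joined combination."""
    tok = str(token).strip()
    if tok.lower() in _MISSING_TOKENS:
        return None
    parts = tok.split("-")
    if len(parts) != copy_number:
        raise AlleleError(
            f"token {token!r} has {len(parts)} allele(s), locus expects {copy_number}"
        )
    values = [parse_allele_token(p) for p in parts]
    if any(v is None for v in values):
        return None
    return locus_call([v for v in values if v is not None])


def format_locus_call(call: LocusCall | None) -> str:
    if call is None:
        return ""

    def fmt(v: float) -> str:
        return str(int(v)) if float(v).is_integer() else f"{v:g}"

    return "-".join(fmt(v) for v in call)


def derive_dys389b(dys389I: float | None, dys389II: float | None) -> float | None:
    """DYS389b = DYS389II - DYS389I; missing inputs propagate."""
    if dys389I is None or dys389II is None:
        return None
    diff = float(dys389II) - float(dys389I)
    if diff <= 0:
        raise AlleleError(
            f"DYS389b derivation gives non-positive repeat count ({dys389II} - {dys389I})"
        )
    return check_allele(diff)


def _sniff_sep(path: Path) -> str:
    header = path.open().readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_haplotype_table(
    path: str | Path,
    panel: LocusPanel | None = None,
    strict: bool = True,
) -> PopulationDataset:
    """Read and validate a per-individual haplotype table.

    With ``strict`` (default) any bad row raises a :class:`RowError` naming
    the offending line; with ``strict=False`` bad rows are dropped and their
    diagnostics collected on the returned dataset as ``rejected`` (a list of
    (row, message) pairs).
    """
    panel = panel or default_panel()
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)

    for col in META_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    has_389ii = "DYS389II" in df.columns
    for loc in panel.locus_names:
        if loc not in df.columns and not (loc == "DYS389b" and has_389ii):
            raise FormatError(f"missing locus column {loc!r}")

    samples: list[SampleRecord] = []
    rejected: list[tuple[int, str]] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        try:
            sid = str(rowd["sample_id"]).strip()
            if not sid:
                raise AlleleError("empty sample_id")
            if sid in seen_ids:
                raise AlleleError(f"duplicate sample_id {sid!r}")
            lat = float(rowd["latitude"])
            lon = float(rowd["longitude"])
            if not (-90 <= lat <= 90) or not (-180 <= lon <= 180):
                raise AlleleError(f"coordinates out of range ({lat}, {lon})")
            alleles: dict[str, LocusCall | None] = {}
            for loc in panel.locus_names:
                cn = panel[loc].copy_number
                if loc == "DYS389b" and (loc not in rowd or not str(rowd.get(loc, "")).strip()):
                    a1 = parse_allele_token(rowd.get("DYS389I", ""))
                    a2 = parse_allele_token(rowd.get("DYS389II", ""))
                    b = derive_dys389b(a1, a2)
                    alleles[loc] = None if b is None else (b,)
                else:
                    alleles[loc] = parse_locus_token(rowd.get(loc, ""), cn)
            # consistency check when the table carries all three 389 columns
            if has_389ii and alleles.get("DYS389b") is not None:
                a1 = parse_allele_token(rowd.get("DYS389I", ""))
                a2 = parse_allele_token(rowd.get("DYS389II", ""))
                if a1 is not None and a2 is not None:
                    expected = derive_dys389b(a1, a2)
                    if expected is not None and alleles["DYS389b"] != (expected,):
                        raise AlleleError(
                            f"DYS389b={format_locus_call(alleles['DYS389b'])} "
                            f"inconsistent with DYS389II-DYS389I={expected:g}"
                        )
            seen_ids.add(sid)
            samples.append(
                SampleRecord(
                    sample_id=sid,
                    population=str(rowd["population"]).strip(),
                    ethnicity=str(rowd["ethnicity"]).strip(),
                    latitude=lat,
                    longitude=lon,
                    haplogroup=str(rowd["haplogroup"]).strip(),
                    haplotype=YHaplotype(alleles=alleles),
                )
            )
        except (AlleleError, ValueError) as exc:
            if strict:
                raise RowError(i, str(exc)) from exc
            rejected.append((i, str(exc)))

    ds = PopulationDataset(panel=panel, samples=samples)
    ds.rejected = rejected  # type: ignore[attr-defined]
    return ds


def write_haplotype_table(ds: PopulationDataset, path: str | Path) -> None:
    ds.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ValidationReport:
    """Per-check pass/fail summary for a dataset."""

    checks: dict[str, list[str]] = field(default_factory=dict)

    def add(self, check: str, failure: str | None = None) -> None:
        self.checks.setdefault(check, [])
        if failure is not None:
            self.checks[check].append(failure)

    @property
    def n_failures(self) -> int:
        return sum(len(v) for v in self.checks.values())

    @property
    def passed(self) -> bool:
        return self.n_failures == 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "passed": self.passed,
                "n_failures": self.n_failures,
                "checks": {k: {"passed": not v, "failures": v} for k, v in self.checks.items()},
            },
            indent=2,
        )

    def __str__(self) -> str:
        lines = [f"validation: {'PASS' if self.passed else 'FAIL'} ({self.n_failures} failure(s))"]
        for check, failures in self.checks.items():
            lines.append(f"  [{'ok' if not failures else 'FAIL'}] {check}")
            lines.extend(f"      - {f}" for f in failures)
        return "\n".join(lines)


def validate_dataset(ds: PopulationDataset) -> ValidationReport:
    """Run structural checks; failures are reported, never raised."""
    from .haplogroups import HaplogroupParseError, parse_haplogroup_name

    report = ValidationReport()
    for check in ("locus_completeness", "allele_ranges", "copy_number", "coordinates", "haplogroup_names", "unique_ids"):
        report.add(check)

    seen: set[str] = set()
    for s in ds.samples:
        if s.sample_id in seen:
            report.add("unique_ids", f"duplicate sample_id {s.sample_id!r}")
        seen.add(s.sample_id)
        if not (-90 <= s.latitude <= 90 and -180 <= s.longitude <= 180):
            report.add("coordinates", f"{s.sample_id}: ({s.latitude}, {s.longitude}) out of range")
        for loc in ds.panel.locus_names:
            call = s.haplotype.alleles.get(loc)
            if call is None:
                report.add("locus_completeness", f"{s.sample_id}: missing {loc}")
                continue
            if len(call) != ds.panel[loc].copy_number:
                report.add("copy_number", f"{s.sample_id}: {loc} has {len(call)} allele(s)")
            for v in call:
                try:
                    check_allele(v)
                except AlleleError as exc:
                    report.add("allele_ranges", f"{s.sample_id}: {loc}: {exc}")
        try:
            parse_haplogroup_name(s.haplogroup)
        except HaplogroupParseError as exc:
            report.add("haplogroup_names", f"{s.sample_id}: {exc}")
    return report
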