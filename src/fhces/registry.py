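"""Variant-metadata registry: CCP module, AMD odds ratio, allele frequencies.

The registry mirrors the published table of the 21 most prevalent AMD-linked
factor H variants.  It is annotation only — odds ratios and frequencies ride
along into reports but never enter the efficacy score.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import DuplicateRecordError, ParseError

__all__ = ["VariantRecord", "read_variant_registry", "write_variant_registry",
           "load_builtin_registry"]

#: Tokens accepted as missing values on read (written back as empty cells).
MISSING_TOKENS = {"", "ND", "—", "-", "Not known", "NA", "N/A", "nan"}

REGISTRY_COLUMNS = [
    "variant_name", "ccp_module", "odds_ratio",
    "amd_allele_freq_pct", "gnomad_allele_freq_pct", "dbsnp_id",
]


@dataclass(frozen=True)
class VariantRecord:
    variant_name: str
    ccp_module: str | None = None
    odds_ratio: float | None = None
    amd_allele_freq_pct: float | None = None
    gnomad_allele_freq_pct: float | None = None
    dbsnp_id: str | None = None

    def __post_init__(self):
        for name in ("amd_allele_freq_pct", "gnomad_allele_freq_pct"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ParseError(f"{name} must be >= 0 when present")


def _parse_float(token: str) -> float | None:
    """Numeric cell or missing; qualitative entries (e.g. 'Risk (LOD = 1.22)')
    carry no usable magnitude and parse as missing."""
    token = token.strip()
    if token in MISSING_TOKENS:
        return None
    try:
        v = float(token)
    except ValueError:
        return None
    return v if math.isfinite(v) else None


def _parse_text(token: str) -> str | None:
    token = token.strip()
    return None if token in MISSING_TOKENS else token


def read_variant_registry(path: str | Path) -> list[VariantRecord]:
    """Read a registry TSV.  Missing cells ('ND', '—', 'Not known', empty)
    become None, never zeros; duplicate variant names raise."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [row for row in reader if row and not row[0].startswith("#")]
    if not rows:
        raise ParseError(f"empty registry file: {path}")
    header = [h.strip() for h in rows[0]]
    missing_cols = [c for c in REGISTRY_COLUMNS[:2] if c not in header]
    if missing_cols:
        raise ParseError(f"registry header lacks columns {missing_cols}", line=1)
    idx = {c: header.index(c) for c in REGISTRY_COLUMNS if c in header}
    records, seen = [], set()
    for lineno, row in enumerate(rows[1:], start=2):
        if all(not cell.strip() for cell in row):
            continue
        if len(row) < len(header):
            row = row + [""] * (len(header) - len(row))

        def cell(col: str) -> str:
            return row[idx[col]] if col in idx else ""

        name = cell("variant_name").strip()
        if not name:
            raise ParseError("row lacks a variant_name", line=lineno)
        if name in seen:
            raise DuplicateRecordError(f"duplicate variant name '{name}'")
        seen.add(name)
        try:
            records.append(VariantRecord(
                variant_name=name,
                ccp_module=_parse_text(cell("ccp_module")),
                odds_ratio=_parse_float(cell("odds_ratio")),
                amd_allele_freq_pct=_parse_float(cell("amd_allele_freq_pct")),
                gnomad_allele_freq_pct=_parse_float(cell("gnomad_allele_freq_pct")),
                dbsnp_id=_parse_text(cell("dbsnp_id")),
            ))
        except ParseError as exc:
            raise ParseError(str(exc), line=lineno) from exc
    if not records:
        raise ParseError(f"registry file has a header but no records: {path}")
    return records


def write_variant_registry(records: list[VariantRecord], path: str | Path) -> None:
    """Write a registry TSV; missing values become empty cells."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(REGISTRY_COLUMNS)
        for r in records:
            w.writerow([
                r.variant_name,
                r.ccp_module or "",
                "" if r.odds_ratio is None else repr(r.odds_ratio),
                "" if r.amd_allele_freq_pct is None else repr(r.amd_allele_freq_pct),
                "" if r.gnomad_allele_freq_pct is None else repr(r.gnomad_allele_freq_pct),
                r.dbsnp_id or "",
            ])


def load_builtin_registry() -> list[VariantRecord]:
    """The packaged registry of the 21-variant AMD panel plus the control."""
    with resources.as_file(
        resources.files("fhces.data").joinpath("variant_registry.tsv")
    ) as p:
        return read_variant_registry(p)
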