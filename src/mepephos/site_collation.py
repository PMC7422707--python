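"""Residue-level collation of phosphopeptide evidence.

LC-MS/MS phosphopeptide rows (peptide span, assigned phosphopositions,
spectral count, expect value, mass error) are aggregated into a site map.
A phosphate that could sit on either of two residues ("103 or 104") is
kept as one ambiguous unit and contributes exactly one site to every
total; Ser/Thr tallies are therefore ranges.  Spectral counts printed in
such tables are cumulative over all peptides containing a site, so the
per-site aggregate is the maximum count over rows assigning the site,
never the sum.  Intact-mass (MALDI) ladder evidence is merged at the
region level: when the ladder accounts for at least as many phosphates
as the region has serines (after reserving any attributed to tag
serines), every serine in the region is marked phosphorylated with
status "assumed".
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd


class EvidenceValidationError(ValueError):
    """An evidence row is internally inconsistent (position/residue mismatch)."""


@dataclass(frozen=True)
class PeptideEvidence:
    """One phosphopeptide observation.

    ``site_units`` holds one frozenset per independent phosphate: a
    1-set for a resolved site, a 2-set for an either-or ambiguous pair.
    Positions are printed (mature) numbering.
    """

    residues: str
    start: int
    end: int
    site_units: tuple[frozenset, ...]
    spectral_count: int
    expect: Optional[float] = None
    ppm_error: Optional[float] = None
    conservation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.residues):
            raise EvidenceValidationError(
                f"span {self.start}..{self.end} does not fit "
                f"{len(self.residues)}-mer {self.residues!r}"
            )
        if self.spectral_count < 0:
            raise EvidenceValidationError("spectral count must be >= 0")
        for unit in self.site_units:
            if len(unit) not in (1, 2):
                raise EvidenceValidationError(
                    f"site unit {sorted(unit)} must have 1 or 2 positions"
                )
            for pos in unit:
                if not self.start <= pos <= self.end:
                    raise EvidenceValidationError(
                        f"phospho position {pos} outside peptide span "
                        f"{self.start}..{self.end}"
                    )

    def residue_at(self, pos: int) -> str:
        return self.residues[pos - self.start]


def parse_site_field(text: str) -> tuple[frozenset, ...]:
    """Parse e.g. ``"42"``, ``"103|104"`` or ``"436;441"`` into site units.

    ';' separates independent phosphates on the same peptide; '|' marks an
    either-or ambiguous pair within one phosphate.
    """
    units = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        positions = frozenset(int(p) for p in chunk.split("|"))
        units.append(positions)
    return tuple(units)


def format_site_unit(unit: frozenset) -> str:
    return "|".join(str(p) for p in sorted(unit))


def read_evidence_table(path) -> list[PeptideEvidence]:
    """Read a delimited evidence table.

    Expected columns: peptide, start, end, phospho, counts, expect, ppm,
    conservation (last three optional).  Tab- or comma-delimited.
    """
    rows = []
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delim)
        for rec in reader:
            rows.append(
                PeptideEvidence(
                    residues=rec["peptide"].strip().upper(),
                    start=int(rec["start"]),
                    end=int(rec["end"]),
                    site_units=parse_site_field(rec["phospho"]),
                    spectral_count=int(rec["counts"]),
                    expect=float(rec["expect"]) if rec.get("expect") else None,
                    ppm_error=float(rec["ppm"]) if rec.get("ppm") else None,
                    conservation=rec.get("conservation") or None,
                )
            )
    return rows


@dataclass(frozen=True)
class SiteEntry:
    """One distinct phosphosite (possibly an unresolved either-or pair)."""

    positions: tuple[int, ...]  # sorted; length 1 (resolved) or 2 (ambiguous)
    residues: tuple[str, ...]  # letters at those positions
    status: str  # "phosphorylated" | "assumed"
    source: str  # "LCMS" | "MALDI" | "both"
    spectral_count: int
    major: bool = False

    @property
    def ambiguous(self) -> bool:
        return len(self.positions) > 1

    @property
    def key(self) -> tuple[int, ...]:
        return self.positions


@dataclass
class SiteMap:
    """Residue-level aggregation of phosphosite evidence."""

    entries: dict = field(default_factory=dict)  # key -> SiteEntry
    partial_regions: list = field(default_factory=list)
    tag_sites: list = field(default_factory=list)  # tag-local notes, outside totals

    @property
    def n_sites(self) -> int:
        return len(self.entries)

    def sorted_entries(self) -> list[SiteEntry]:
        return [self.entries[k] for k in sorted(self.entries)]

    def residue_class_tally(self) -> dict:
        """Min/max counts of Ser and Thr sites, ranges reflecting ambiguity."""
        ser_min = ser_max = thr_min = thr_max = 0
        for entry in self.entries.values():
            letters = set(entry.residues)
            if letters == {"S"}:
                ser_min += 1
                ser_max += 1
            elif letters == {"T"}:
                thr_min += 1
                thr_max += 1
            else:  # mixed either-or pair: counts toward either tally's max
                if "S" in letters:
                    ser_max += 1
                if "T" in letters:
                    thr_max += 1
        return {
            "ser_min": ser_min,
            "ser_max": ser_max,
            "thr_min": thr_min,
            "thr_max": thr_max,
        }


def _validate_row(
    row: PeptideEvidence, parent_sequence: Optional[str], index: int
) -> None:
    for unit in row.site_units:
        for pos in unit:
            aa = row.residue_at(pos)
            if aa not in "ST":
                raise EvidenceValidationError(
                    f"row {index}: position {pos} is {aa!r}, not a "
                    "phospho-accepting S/T"
                )
    if parent_sequence is not None:
        sub = parent_sequence[row.start - 1 : row.end]
        if sub != row.residues:
            raise EvidenceValidationError(
                f"row {index}: peptide {row.residues!r} does not match parent "
                f"sequence at {row.start}..{row.end} ({sub!r})"
            )


def collate_lcms(
    evidence: Iterable[PeptideEvidence],
    parent_sequence: Optional[str] = None,
) -> SiteMap:
    """Aggregate evidence rows into a site map.

    Each distinct site unit becomes one entry; its aggregated spectral
    count is the maximum over the rows carrying it.
    """
    site_map = SiteMap()
    for i, row in enumerate(evidence, start=1):
        _validate_row(row, parent_sequence, i)
        for unit in row.site_units:
            key = tuple(sorted(unit))
            letters = tuple(row.residue_at(p) for p in key)
            prev = site_map.entries.get(key)
            count = row.spectral_count if prev is None else max(
                prev.spectral_count, row.spectral_count
            )
            site_map.entries[key] = SiteEntry(
                positions=key,
                residues=letters,
                status="phosphorylated",
                source="LCMS",
                spectral_count=count,
            )
    return site_map


DEFAULT_MAJOR_THRESHOLD = 20


def classify_major(
    site_map: SiteMap, threshold: int = DEFAULT_MAJOR_THRESHOLD
) -> set[int]:
    """Positions of sites whose aggregated spectral count >= threshold.

    Returns the union of positions of qualifying units and flips the
    ``major`` flag on those entries in place.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    major_positions: set[int] = set()
    for key, entry in site_map.entries.items():
        is_major = (
            entry.status == "phosphorylated"
            and entry.spectral_count >= threshold
        )
        site_map.entries[key] = replace(entry, major=is_major)
        if is_major:
            major_positions.update(entry.positions)
    return major_positions


def merge_maldi(
    site_map: SiteMap,
    region_serines: Sequence[int],
    ladder_max: int,
    tag_serine_count: int = 0,
    parent_residue: str = "S",
) -> SiteMap:
    """Merge an intact-mass ladder result over a serine-rich region.

    If the ladder's highest phosphate count, minus any phosphates
    attributed to tag serines, covers every serine in the region, all
    region serines are marked phosphorylated ("assumed", region-level
    evidence); otherwise the region is recorded as partially
    phosphorylated with no site-level assignment.
    """
    if ladder_max < 0:
        raise ValueError("ladder_max must be >= 0")
    out = SiteMap(
        entries=dict(site_map.entries),
        partial_regions=list(site_map.partial_regions),
        tag_sites=list(site_map.tag_sites),
    )
    if tag_serine_count:
        out.tag_sites.append(
            {"n_serines": tag_serine_count, "source": "MALDI", "status": "assumed"}
        )
    effective = ladder_max - tag_serine_count
    if ladder_max == 0:
        return out
    if effective >= len(region_serines):
        for pos in region_serines:
            key = (pos,)
            prev = out.entries.get(key)
            if prev is not None:
                out.entries[key] = replace(prev, source="both")
            else:
                out.entries[key] = SiteEntry(
                    positions=key,
                    residues=(parent_residue,),
                    status="assumed",
                    source="MALDI",
                    spectral_count=0,
                )
    else:
        out.partial_regions.append(
            {
                "serines": tuple(region_serines),
                "ladder_max": ladder_max,
                "tag_serine_count": tag_serine_count,
            }
        )
    return out


def totals(site_map: SiteMap) -> dict:
    """Headline counts: LC-MS/MS sites, MALDI region sites, grand total.

    Tag sites are reported separately and excluded from the grand total;
    each ambiguous pair counts once.
    """
    lcms = sum(1 for e in site_map.entries.values() if e.source in ("LCMS", "both"))
    maldi = sum(1 for e in site_map.entries.values() if e.source == "MALDI")
    return {
        "lcms_sites": lcms,
        "maldi_region_sites": maldi,
        "grand_total": site_map.n_sites,
        "tag_sites": sum(t["n_serines"] for t in site_map.tag_sites),
    }


def site_map_to_frame(site_map: SiteMap) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "positions": "|".join(str(p) for p in e.positions),
                "residues": "".join(e.residues),
                "status": e.status,
                "source": e.source,
                "spectral_count": e.spectral_count,
                "major": e.major,
                "ambiguous": e.ambiguous,
            }
            for e in site_map.sorted_entries()
        ]
    )


def site_map_to_json(site_map: SiteMap) -> str:
    payload = {
        "sites": [
            {
                "positions": list(e.positions),
                "residues": list(e.residues),
                "status": e.status,
                "source": e.source,
                "spectral_count": e.spectral_count,
                "major": e.major,
            }
            for e in site_map.sorted_entries()
        ],
        "partial_regions": [
            {**r, "serines": list(r["serines"])} for r in site_map.partial_regions
        ],
        "tag_sites": site_map.tag_sites,
        "totals": totals(site_map),
    }
    return json.dumps(payload, indent=2)
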