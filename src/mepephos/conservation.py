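"""Phosphosite conservation across an ortholog alignment.

Reference-sequence positions are mapped through a multiple sequence
alignment to their columns, and per-site conservation is the percentage
of aligned sequences (reference included) carrying the identical residue
at that column.  With 14 mammalian sequences the printed percentages are
integer roundings of k/14 (93 = 13/14, 86 = 12/14, ...); a gap at the
focal column counts as a non-match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO

GAP = "-"


@dataclass(frozen=True)
class Alignment:
    """Aligned records (id, gapped residues), equal gapped lengths."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs at least two records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError("aligned records must share one gapped length")

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    def record(self, record_id: str) -> str:
        for rid, seq in self.records:
            if rid == record_id:
                return seq
        raise KeyError(f"record {record_id!r} not in alignment")

    def ungapped(self, record_id: str) -> str:
        return self.record(record_id).replace(GAP, "")


def read_alignment(path) -> Alignment:
    aln = AlignIO.read(str(path), "fasta")
    return Alignment(tuple((rec.id, str(rec.seq).upper()) for rec in aln))


def map_position_to_column(aln: Alignment, ref_id: str, ref_pos: int) -> int:
    """1-based alignment column of the ref_pos-th non-gap reference residue."""
    gapped = aln.record(ref_id)
    count = 0
    for col, aa in enumerate(gapped, start=1):
        if aa != GAP:
            count += 1
            if count == ref_pos:
                return col
    raise IndexError(
        f"position {ref_pos} beyond ungapped length {count} of {ref_id!r}"
    )


def map_column_to_position(aln: Alignment, ref_id: str, column: int) -> int:
    """Inverse of map_position_to_column; the column must hold a residue."""
    gapped = aln.record(ref_id)
    if not 1 <= column <= len(gapped):
        raise IndexError(f"column {column} outside alignment")
    if gapped[column - 1] == GAP:
        raise ValueError(f"column {column} is a gap in {ref_id!r}")
    return sum(1 for aa in gapped[:column] if aa != GAP)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SiteConservation:
    ref_position: int
    column: int
    ref_residue: str
    n_match: int
    n_total: int
    percent: int
    match_flags: tuple[tuple[str, bool], ...]


def site_conservation(
    aln: Alignment,
    ref_id: str,
    sites: Iterable[int],
) -> list[SiteConservation]:
    """Conservation of each reference site across all aligned records.

    The match rule is exact residue identity at the mapped column (an
    aligned Thr does not count for a Ser site); the denominator includes
    the reference itself.  Percent is k/N rounded half away from zero.
    """
    out = []
    for pos in sites:
        col = map_position_to_column(aln, ref_id, pos)
        ref_aa = aln.record(ref_id)[col - 1]
        flags = tuple(
            (rid, seq[col - 1] == ref_aa) for rid, seq in aln.records
        )
        n_match = sum(1 for _, ok in flags if ok)
        out.append(
            SiteConservation(
                ref_position=pos,
                column=col,
                ref_residue=ref_aa,
                n_match=n_match,
                n_total=aln.n_records,
                percent=_round_half_away(100.0 * n_match / aln.n_records),
                match_flags=flags,
            )
        )
    return out


def conservation_to_frame(records: Sequence[SiteConservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "position": r.ref_position,
                "column": r.column,
                "residue": r.ref_residue,
                "n_match": r.n_match,
                "n_total": r.n_total,
                "percent": r.percent,
            }
            for r in records
        ]
    )
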