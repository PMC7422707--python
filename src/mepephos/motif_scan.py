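"""FAM20C recognition-motif scanning.

FAM20C, the Golgi kinase that phosphorylates most secreted
phosphoproteins, recognises Ser-x-Glu and its phospho-primed variant
Ser-x-pSer; related acidic contexts (Ser-x-Asp, and acidic residues at
n+5..n+7 as in the SxQxxDEE-type motif) are also phosphorylated in
SIBLING proteins.  Scanners work on printed positions: a chain scanned
with offset 489 reports matches at 493, not 5.

Serine-only scanning is the default; threonine can be enabled, but the
motif analysis in this system concerns serines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, Union

from .sequence_model import ProteinChain

ACIDIC = frozenset("DE")


def _seq_and_offset(chain: Union[ProteinChain, str], offset: int = 1) -> tuple[str, int]:
    if isinstance(chain, ProteinChain):
        return chain.residues, chain.numbering_offset
    return chain, offset


def _site_letters(include_threonine: bool) -> frozenset:
    return frozenset("ST") if include_threonine else frozenset("S")


def scan_canonical(
    chain: Union[ProteinChain, str],
    offset: int = 1,
    include_threonine: bool = False,
) -> set[int]:
    """Positions n with Ser at n and Glu at n+2 (the canonical S-x-E motif)."""
    seq, off = _seq_and_offset(chain, offset)
    letters = _site_letters(include_threonine)
    return {
        off + i
        for i in range(len(seq) - 2)
        if seq[i] in letters and seq[i + 2] == "E"
    }


def scan_extended(
    chain: Union[ProteinChain, str],
    phospho_positions: Iterable[int] = (),
    offset: int = 1,
    include_threonine: bool = False,
) -> set[int]:
    """Fixed point of S-x-E plus phospho-priming S-x-pS propagation.

    Seeded with the direct S-x-E matches and any externally known
    phosphopositions; a serine at n is added whenever position n+2 is in
    the set (Ser-x-pSer).  The set grows monotonically and is bounded by
    the serine positions, so iteration terminates at the smallest fixed
    point containing the seed.
    """
    seq, off = _seq_and_offset(chain, offset)
    letters = _site_letters(include_threonine)
    phospho = set(phospho_positions)
    for p in phospho:
        if not off <= p <= off + len(seq) - 1:
            raise ValueError(f"phospho position {p} outside scanned sequence")
    current = scan_canonical(seq, off, include_threonine) | phospho
    while True:
        added = {
            off + i
            for i in range(len(seq))
            if seq[i] in letters and (off + i + 2) in current
        } - current
        if not added:
            return current
        current |= added


def scan_sxd(
    chain: Union[ProteinChain, str],
    offset: int = 1,
    include_threonine: bool = False,
) -> set[int]:
    """Positions n with Ser at n and Asp at n+2 (S-x-D motif)."""
    seq, off = _seq_and_offset(chain, offset)
    letters = _site_letters(include_threonine)
    return {
        off + i
        for i in range(len(seq) - 2)
        if seq[i] in letters and seq[i + 2] == "D"
    }


def scan_acidic_context(
    chain: Union[ProteinChain, str],
    offset: int = 1,
    include_threonine: bool = False,
    require_q_at_2: bool = False,
    require_all_acidic: bool = False,
) -> set[int]:
    """Ser positions with acidic residue(s) at n+5..n+7.

    The generalized form of the SxQxxDEE-type motif: by default one
    D/E anywhere in the n+5..n+7 window qualifies.  The literal strict
    motif (Gln at n+2 and the whole window acidic) is available via flags.
    Window positions past the chain terminus simply cannot match.
    """
    seq, off = _seq_and_offset(chain, offset)
    letters = _site_letters(include_threonine)
    out = set()
    for i in range(len(seq)):
        if seq[i] not in letters:
            continue
        if require_q_at_2 and not (i + 2 < len(seq) and seq[i + 2] == "Q"):
            continue
        window = [seq[i + d] for d in (5, 6, 7) if i + d < len(seq)]
        if require_all_acidic:
            ok = len(window) == 3 and all(aa in ACIDIC for aa in window)
        else:
            ok = any(aa in ACIDIC for aa in window)
        if ok:
            out.add(off + i)
    return out


@dataclass(frozen=True)
class SiteAnnotation:
    """Per-residue motif classes and phospho status with provenance."""

    position: int
    residue: str
    motif_classes: FrozenSet[str]
    phospho_status: str = "not observed"  # observed | not observed | assumed
    evidence_source: str = ""  # LCMS | MALDI | both | ""


def annotate_sites(
    chain: Union[ProteinChain, str],
    offset: int = 1,
    phospho_positions: Iterable[int] = (),
    include_threonine: bool = False,
) -> list[SiteAnnotation]:
    """Motif-class annotation for every Ser (optionally Thr) in the chain."""
    seq, off = _seq_and_offset(chain, offset)
    letters = _site_letters(include_threonine)
    phospho = set(phospho_positions)
    sxe = scan_canonical(seq, off, include_threonine)
    sxps = scan_extended(seq, phospho, off, include_threonine) if phospho else set()
    sxd = scan_sxd(seq, off, include_threonine)
    acidic = scan_acidic_context(seq, off, include_threonine)
    annotations = []
    for i, aa in enumerate(seq):
        if aa not in letters:
            continue
        pos = off + i
        classes = set()
        if pos in sxe:
            classes.add("SxE")
        if pos in sxps and pos not in sxe:
            classes.add("SxpS")
        if pos in sxd:
            classes.add("SxD")
        if pos in acidic:
            classes.add("acidic_n5_n7")
        annotations.append(
            SiteAnnotation(
                position=pos,
                residue=aa,
                motif_classes=frozenset(classes),
                phospho_status="observed" if pos in phospho else "not observed",
                evidence_source="LCMS" if pos in phospho else "",
            )
        )
    return annotations
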