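"""In-silico tryptic digestion with missed cleavages.

Trypsin cleaves C-terminal to Lys/Arg unless the next residue is Pro.
Peptides are enumerated for 0..max_missed internal missed cleavages and
carry parent coordinates in printed numbering, so the K509A/K515A
tail mutation's effect (loss of two cleavage sites, hence one long
ASARM-spanning C-terminal peptide) falls out of the site diff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet

import pandas as pd

from .sequence_model import Construct, ProteinChain, assemble_construct


@dataclass(frozen=True)
class CleavageRule:
    """Residues cut after, and next-residues that block the cut."""

    cut_after: FrozenSet[str] = frozenset("KR")
    blocked_by_next: FrozenSet[str] = frozenset("P")

    def __post_init__(self) -> None:
        if not self.cut_after:
            raise ValueError("cut_after must be non-empty")


TRYPSIN = CleavageRule()


@dataclass(frozen=True)
class Peptide:
    """A digestion product with parent coordinates (1-based inclusive)."""

    parent_id: str
    start: int
    end: int
    residues: str
    missed_cleavages: int

    def __len__(self) -> int:
        return len(self.residues)


def cleavage_sites(chain: ProteinChain, rule: CleavageRule = TRYPSIN) -> list[int]:
    """Printed positions after which the chain is cut (chain end excluded)."""
    seq = chain.residues
    sites = []
    for i in range(len(seq) - 1):
        if seq[i] in rule.cut_after and seq[i + 1] not in rule.blocked_by_next:
            sites.append(chain.numbering_offset + i)
    return sites


def trypsin_digest(
    chain: ProteinChain,
    rule: CleavageRule = TRYPSIN,
    max_missed: int = 2,
) -> list[Peptide]:
    """All tryptic peptides with up to ``max_missed`` internal missed sites.

    Fully-cleaved products are the spans between consecutive cut sites; a
    peptide with m missed cleavages is the concatenation of m+1 adjacent
    fully-cleaved products.  Output is sorted by start, then length.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    sites = cleavage_sites(chain, rule)
    # boundaries as printed positions: fragment i spans (bounds[i], bounds[i+1]]
    bounds = [chain.start - 1] + sites + [chain.end]
    n_frag = len(bounds) - 1
    peptides = []
    for i in range(n_frag):
        for m in range(min(max_missed, n_frag - 1 - i) + 1):
            start = bounds[i] + 1
            end = bounds[i + m + 1]
            lo = start - chain.numbering_offset
            hi = end - chain.numbering_offset + 1
            peptides.append(
                Peptide(chain.id, start, end, chain.residues[lo:hi], m)
            )
    peptides.sort(key=lambda p: (p.start, len(p)))
    return peptides


@dataclass(frozen=True)
class MutationEffectReport:
    """Cleavage sites gained/lost by mutating a construct."""

    lost_sites: tuple[int, ...]  # present in WT, absent in mutant
    gained_sites: tuple[int, ...]

    @property
    def is_empty(self) -> bool:
        return not self.lost_sites and not self.gained_sites


def explain_mutation_effect(
    wt: Construct, mut: Construct, rule: CleavageRule = TRYPSIN
) -> MutationEffectReport:
    """Diff the tryptic cleavage sites of two constructs on the same base."""
    if len(wt.base) != len(mut.base):
        raise ValueError("constructs must share the same base chain length")
    wt_sites = set(cleavage_sites(assemble_construct(wt), rule))
    mut_sites = set(cleavage_sites(assemble_construct(mut), rule))
    return MutationEffectReport(
        lost_sites=tuple(sorted(wt_sites - mut_sites)),
        gained_sites=tuple(sorted(mut_sites - wt_sites)),
    )


def peptides_to_frame(peptides: list[Peptide]) -> pd.DataFrame:
    """Peptide table as a DataFrame (parent, start, end, sequence, missed)."""
    return pd.DataFrame(
        [
            {
                "parent": p.parent_id,
                "start": p.start,
                "end": p.end,
                "sequence": p.residues,
                "missed": p.missed_cleavages,
            }
            for p in peptides
        ]
    )
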