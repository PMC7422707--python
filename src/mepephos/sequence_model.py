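"""Protein chains, recombinant constructs and coordinate bookkeeping.

Human MEPE is a 508-residue secreted SIBLING protein; every position in
this package is reported in that mature-chain numbering (1-based,
inclusive), which is the numbering used for all phosphosite calls.  The
recombinant form studied here carries a C-terminal KLGP linker, a myc
epitope (EQKLISEEDL), an NSAVD linker and a His6 tag; the lysines at
(continued) positions 509 and 515 of that tail can be mutated to alanine
so that trypsin yields one long C-terminal peptide spanning the ASARM.

Tag residues are addressed both by segment name + local index and by
continuing the mature numbering through the tags, because the two
mutated lysines are conventionally written K509A and K515A.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class MutationMismatchError(ValueError):
    """A point mutation's stated wild-type residue disagrees with the chain."""


@dataclass(frozen=True)
class ProteinChain:
    """An ungapped amino-acid chain with a printed-numbering offset.

    ``numbering_offset`` is the printed position of residue 1, so the
    printed position of residue i (1-based) is ``numbering_offset + i - 1``.
    """

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("chain must contain at least one residue")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-canonical residues in {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def start(self) -> int:
        """Printed position of the first residue."""
        return self.numbering_offset

    @property
    def end(self) -> int:
        """Printed position of the last residue."""
        return self.numbering_offset + len(self.residues) - 1

    def residue_at(self, printed_pos: int) -> str:
        """Residue letter at a printed position."""
        if not self.start <= printed_pos <= self.end:
            raise IndexError(
                f"position {printed_pos} outside chain {self.id!r} "
                f"({self.start}..{self.end})"
            )
        return self.residues[printed_pos - self.numbering_offset]

    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class PointMutation:
    """Single-residue substitution at a printed position, e.g. K509A."""

    position: int
    from_residue: str
    to_residue: str

    @classmethod
    def parse(cls, text: str) -> "PointMutation":
        m = _MUTATION_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse mutation {text!r} (expected e.g. K509A)")
        return cls(position=int(m.group(2)), from_residue=m.group(1), to_residue=m.group(3))

    def __str__(self) -> str:
        return f"{self.from_residue}{self.position}{self.to_residue}"


@dataclass(frozen=True)
class Region:
    """Named 1-based inclusive span in mature numbering (e.g. the ASARM)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid region {self.name!r}: {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ResidueCoordinate:
    """Where one assembled-construct residue lives: segment + printed position."""

    segment: str
    local_index: int  # 1-based within the segment
    printed_position: int  # mature numbering, continued through tags


@dataclass
class Construct:
    """A base chain plus ordered tag segments, with point mutations.

    Mutations are given in continued printed numbering (base numbering
    extended through the concatenated tags), matching the conventional
    K509A/K515A notation for tail mutations.
    """

    base: ProteinChain
    mutations: Sequence[PointMutation] = field(default_factory=tuple)
    tag_segments: Sequence[tuple[str, str]] = field(default_factory=tuple)

    def assemble(self) -> tuple[ProteinChain, list[ResidueCoordinate]]:
        """Return the full chain and a per-residue coordinate table."""
        parts = [("base", self.base.residues)]
        parts.extend(self.tag_segments)
        coords: list[ResidueCoordinate] = []
        printed = self.base.numbering_offset
        letters: list[str] = []
        for name, seq in parts:
            for i, aa in enumerate(seq, start=1):
                coords.append(ResidueCoordinate(name, i, printed))
                letters.append(aa)
                printed += 1
        chain = ProteinChain(
            id=f"{self.base.id}|assembled",
            residues="".join(letters),
            numbering_offset=self.base.numbering_offset,
        )
        mutated = apply_mutations(chain, self.mutations)
        return mutated, coords


def apply_mutations(
    chain: ProteinChain, mutations: Iterable[PointMutation]
) -> ProteinChain:
    """Apply point substitutions, checking each stated wild-type residue.

    The returned chain differs from the input exactly at the mutated
    positions; length and numbering are unchanged.
    """
    letters = list(chain.residues)
    for mut in mutations:
        idx = mut.position - chain.numbering_offset
        if not 0 <= idx < len(letters):
            raise IndexError(f"mutation {mut} outside chain {chain.id!r}")
        if letters[idx] != mut.from_residue:
            raise MutationMismatchError(
                f"mutation {mut}: chain {chain.id!r} has "
                f"{letters[idx]!r} at position {mut.position}"
            )
        letters[idx] = mut.to_residue
    if not mutations:
        return chain
    return ProteinChain(chain.id, "".join(letters), chain.numbering_offset)


def assemble_construct(construct: Construct) -> ProteinChain:
    """Assembled, mutated chain of a construct (coordinate table dropped)."""
    chain, _ = construct.assemble()
    return chain


def extract_region(chain: ProteinChain, region: Region) -> str:
    """Inclusive substring of the chain covered by a printed-position region."""
    if region.start < chain.start or region.end > chain.end:
        raise IndexError(
            f"region {region.name!r} ({region.start}..{region.end}) outside "
            f"chain {chain.id!r} ({chain.start}..{chain.end})"
        )
    lo = region.start - chain.numbering_offset
    return chain.residues[lo : lo + len(region)]


def read_fasta(path) -> list[ProteinChain]:
    """Read chains from FASTA; a ``start=N`` token in the description sets
    the numbering offset (defaults to 1)."""
    chains = []
    for rec in SeqIO.parse(str(path), "fasta"):
        offset = 1
        m = re.search(r"\bstart=(\d+)\b", rec.description)
        if m:
            offset = int(m.group(1))
        chains.append(ProteinChain(rec.id, str(rec.seq).upper(), offset))
    return chains


def write_fasta(chains: Iterable[ProteinChain], path) -> None:
    records = [
        SeqRecord(Seq(c.residues), id=c.id, description=f"start={c.numbering_offset}")
        for c in chains
    ]
    SeqIO.write(records, str(path), "fasta")
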