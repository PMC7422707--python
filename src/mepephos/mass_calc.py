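"""Theoretical peptide masses (monoisotopic and average) and phospho-ladders.

Masses are computed from the standard amino-acid residue compositions via
pyteomics; the module adds the modification bookkeeping used here
(phospho on S/T/Y, oxidation on M, carbamidomethyl on C) and the
MH+ convention of linear-mode MALDI, where peptides are observed singly
protonated.  One phosphate adds 79.96633 Da (monoisotopic) or 79.9799 Da
(average); intact-mass phospho-ladders therefore step by ~80 Da.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import FrozenSet, Sequence

from pyteomics import mass as _pmass

PROTON_MASS = 1.007276  # Da

PHOSPHO_DELTA_MONO = 79.96633
PHOSPHO_DELTA_AVG = 79.9799


class MassMode(str, Enum):
    MONOISOTOPIC = "monoisotopic"
    AVERAGE = "average"


class ChargeForm(str, Enum):
    NEUTRAL = "M"
    PROTONATED = "MH+"


@dataclass(frozen=True)
class MassSpec:
    """Mass convention: isotope mode and neutral vs singly-protonated."""

    mode: MassMode = MassMode.AVERAGE
    charge_form: ChargeForm = ChargeForm.PROTONATED


# Conventions used throughout: MALDI comparisons are average MH+ (linear
# mode, singly protonated); everything else defaults to neutral masses.
MALDI_AVERAGE_MHP = MassSpec(MassMode.AVERAGE, ChargeForm.PROTONATED)
NEUTRAL_MONO = MassSpec(MassMode.MONOISOTOPIC, ChargeForm.NEUTRAL)


@dataclass(frozen=True)
class Modification:
    name: str
    delta_mono: float
    delta_avg: float
    targets: FrozenSet[str]

    def delta(self, mode: MassMode) -> float:
        return self.delta_mono if mode is MassMode.MONOISOTOPIC else self.delta_avg


PHOSPHO = Modification("phospho", PHOSPHO_DELTA_MONO, PHOSPHO_DELTA_AVG, frozenset("STY"))
OXIDATION = Modification("oxidation", 15.99491, 15.9994, frozenset("M"))
CARBAMIDOMETHYL = Modification("carbamidomethyl", 57.02146, 57.0513, frozenset("C"))

MODIFICATIONS = {m.name: m for m in (PHOSPHO, OXIDATION, CARBAMIDOMETHYL)}


def peptide_mass(
    residues: str,
    mods: Sequence[tuple[Modification, int]] = (),
    spec: MassSpec = MassSpec(),
) -> float:
    """Mass of a peptide with positioned modifications.

    ``mods`` holds (modification, position) pairs with 1-based positions in
    the peptide; each position must carry a residue the modification
    targets.  Mass = sum of residue masses + water (+ proton for MH+)
    + modification deltas.
    """
    if not residues:
        raise ValueError("empty peptide")
    for mod, pos in mods:
        if not 1 <= pos <= len(residues):
            raise ValueError(f"{mod.name} position {pos} outside peptide")
        aa = residues[pos - 1]
        if aa not in mod.targets:
            raise ValueError(
                f"{mod.name} cannot target {aa!r} at position {pos} "
                f"(allowed: {''.join(sorted(mod.targets))})"
            )
    average = spec.mode is MassMode.AVERAGE
    m = _pmass.calculate_mass(sequence=residues, average=average)
    m += sum(mod.delta(spec.mode) for mod, _ in mods)
    if spec.charge_form is ChargeForm.PROTONATED:
        m += PROTON_MASS
    return m


def phospho_delta(mode: MassMode) -> float:
    return PHOSPHO.delta(mode)


def phospho_ladder(
    base_mass: float, n_max: int, spec: MassSpec = MassSpec()
) -> list[float]:
    """Theoretical masses [base + k*Δp for k = 0..n_max].

    ``base_mass`` must already be in the charge form of ``spec``; adding
    phosphates does not change the charge form.
    """
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    dp = phospho_delta(spec.mode)
    return [base_mass + k * dp for k in range(n_max + 1)]
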