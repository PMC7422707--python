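"""Matching observed MALDI peaks to phospho-ladders.

An intact phosphopeptide measured in linear mode appears as a ladder of
peaks spaced ~80 Da above the unmodified MH+; assigning each observed
peak to its nearest ladder rung yields a per-peak phosphate count.  A
dephosphorylation (alkaline phosphatase) control collapses the ladder
back to the unmodified mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .mass_calc import MassMode, phospho_delta


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")


@dataclass(frozen=True)
class Tolerance:
    """Either relative (fraction of m/z) or absolute (Da) match tolerance."""

    value: float
    relative: bool = True

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("tolerance must be positive")

    def window(self, mz: float) -> float:
        return self.value * mz if self.relative else self.value


# 0.1% of m/z: appropriate for externally calibrated linear-mode MALDI,
# where observed-vs-theoretical gaps of a few Da at ~5 kDa are routine.
DEFAULT_TOLERANCE = Tolerance(0.001, relative=True)


@dataclass(frozen=True)
class LadderAssignment:
    observed: float
    n_phospho: int
    theoretical: float
    error_da: float
    error_ppm: float


@dataclass(frozen=True)
class LadderResult:
    assignments: tuple[LadderAssignment, ...]
    unassigned: tuple[float, ...]


def read_peaklist(path) -> list[Peak]:
    """Two-column delimited text (m/z [, intensity]); '#' comments allowed."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            mz = float(parts[0])
            intensity = float(parts[1]) if len(parts) > 1 else None
            peaks.append(Peak(mz, intensity))
    return peaks


def _as_peaks(peaks: Iterable) -> list[Peak]:
    out = []
    for p in peaks:
        if isinstance(p, Peak):
            out.append(p)
        elif isinstance(p, (int, float)):
            out.append(Peak(float(p)))
        else:
            mz, intensity = p
            out.append(Peak(float(mz), intensity))
    return out


def assign_phospho_ladder(
    peaks: Iterable,
    base_mass: float,
    tolerance: Tolerance = DEFAULT_TOLERANCE,
    mode: MassMode = MassMode.AVERAGE,
    intensity_floor: Optional[float] = None,
) -> LadderResult:
    """Assign each peak a phosphate count against the ladder on ``base_mass``.

    Each peak goes to its nearest rung k = round((mz - base)/Δp), k >= 0;
    a peak exactly between two rungs takes the lower k (conservative
    phosphate counting).  Peaks farther than the tolerance window from
    every rung are reported unassigned.
    """
    if base_mass <= 0:
        raise ValueError("base_mass must be positive")
    dp = phospho_delta(mode)
    assignments = []
    unassigned = []
    for peak in _as_peaks(peaks):
        if intensity_floor is not None and (
            peak.intensity is None or peak.intensity < intensity_floor
        ):
            continue
        x = (peak.mz - base_mass) / dp
        # nearest rung; an (effectively) equidistant peak takes the lower k
        k_lo = max(0, math.floor(x))
        k_hi = k_lo + 1
        k = k_hi if (k_hi - x) < (x - k_lo) - 1e-9 else k_lo
        theoretical = base_mass + k * dp
        err = peak.mz - theoretical
        if abs(err) <= tolerance.window(peak.mz):
            assignments.append(
                LadderAssignment(
                    observed=peak.mz,
                    n_phospho=k,
                    theoretical=theoretical,
                    error_da=err,
                    error_ppm=1e6 * err / theoretical,
                )
            )
        else:
            unassigned.append(peak.mz)
    return LadderResult(tuple(assignments), tuple(unassigned))


def max_phospho(result: LadderResult) -> int:
    """Highest assigned phosphate count; 0 when nothing is assigned."""
    if not result.assignments:
        return 0
    return max(a.n_phospho for a in result.assignments)


@dataclass(frozen=True)
class DephosphoControlReport:
    passed: bool
    max_before: int
    max_after: int
    n_after_assigned: int


def dephospho_control(
    before: Iterable,
    after: Iterable,
    base_mass: float,
    tolerance: Tolerance = DEFAULT_TOLERANCE,
    mode: MassMode = MassMode.AVERAGE,
) -> DephosphoControlReport:
    """Check that phosphatase treatment collapses the ladder.

    Passes iff the pre-treatment spectrum shows at least one phosphorylated
    rung (k > 0) and every assigned post-treatment peak sits on the
    unmodified rung (k = 0).
    """
    res_before = assign_phospho_ladder(before, base_mass, tolerance, mode)
    res_after = assign_phospho_ladder(after, base_mass, tolerance, mode)
    mb = max_phospho(res_before)
    ma = max_phospho(res_after)
    passed = mb > 0 and ma == 0 and len(res_after.assignments) > 0
    return DephosphoControlReport(
        passed=passed,
        max_before=mb,
        max_after=ma,
        n_after_assigned=len(res_after.assignments),
    )


def assignments_to_frame(result: LadderResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "observed_mz": a.observed,
                "n_phospho": a.n_phospho,
                "theoretical": a.theoretical,
                "error_da": a.error_da,
                "error_ppm": a.error_ppm,
            }
            for a in result.assignments
        ]
    )
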