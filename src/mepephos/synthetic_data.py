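"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of the real inputs —
proteins with planted kinase motifs, ortholog families with per-column
substitution, intact-mass phospho-ladders with Gaussian mass noise and
spurious peaks, and phosphopeptide evidence tables with overdispersed
spectral counts and either-or localization ambiguity — each paired with
a truth record so consuming modules can be tested against known ground
truth without any external data.

All randomness flows from a single integer seed through
numpy.random.Generator; the same seed reproduces every artifact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .conservation import Alignment
from .digestion import TRYPSIN, Peptide, trypsin_digest
from .mass_calc import MassMode, phospho_delta
from .maldi_assign import Peak
from .motif_scan import scan_canonical, scan_sxd
from .sequence_model import ProteinChain
from .site_collation import PeptideEvidence

# background alphabet without S/T/D/E so planted motifs stay the only matches
_NEUTRAL_ALPHABET = "ACFGHIKLMNPQRVWY"


@dataclass
class SimulationConfig:
    """Knobs for all generators; every probability in [0, 1]."""

    seed: int = 0
    # protein generator
    length: int = 120
    n_sxe: int = 4
    n_sxd: int = 3
    # ortholog family
    family_size: int = 14
    substitution_prob: float = 0.07
    # peak-list generator
    base_mass: float = 4838.8
    true_phospho_counts: tuple = (0, 1, 2, 3)
    mass_sigma: float = 0.3
    noise_peak_rate: float = 0.0  # expected number of spurious peaks
    mass_mode: MassMode = MassMode.AVERAGE
    # evidence-table generator
    n_true_sites: int = 6
    count_mean: float = 8.0
    count_dispersion: float = 1.5
    ambiguity_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("substitution_prob", "ambiguity_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class ProteinTruth:
    sxe_positions: frozenset
    sxd_positions: frozenset


def gen_protein(cfg: SimulationConfig) -> tuple[ProteinChain, ProteinTruth]:
    """Random chain containing exactly the planted S-x-E / S-x-D motifs.

    The background alphabet excludes S, T, D and E, so the only possible
    matches are the planted tri-residue motifs; plantings are spaced at
    least 4 residues apart to rule out overlap artifacts, and the result
    is collision-checked by re-scanning.
    """
    if cfg.length < 10:
        raise ValueError("length must be >= 10")
    n_motifs = cfg.n_sxe + cfg.n_sxd
    # each motif occupies 3 residues and needs a 4-residue exclusion zone
    if n_motifs * 5 + 3 > cfg.length:
        raise ValueError(
            f"cannot plant {n_motifs} motifs in a {cfg.length}-mer"
        )
    rng = cfg.rng()
    letters = list(rng.choice(list(_NEUTRAL_ALPHABET), size=cfg.length))
    # pick non-overlapping anchor indices (0-based) at least 5 apart
    anchors: list[int] = []
    candidates = list(range(0, cfg.length - 2))
    rng.shuffle(candidates)
    for idx in candidates:
        if len(anchors) == n_motifs:
            break
        if all(abs(idx - a) >= 5 for a in anchors):
            anchors.append(idx)
    if len(anchors) < n_motifs:
        raise ValueError("could not place all motifs without overlap")
    sxe, sxd = set(), set()
    for j, idx in enumerate(anchors):
        target = "E" if j < cfg.n_sxe else "D"
        letters[idx] = "S"
        letters[idx + 1] = rng.choice(list(_NEUTRAL_ALPHABET))
        letters[idx + 2] = target
        (sxe if target == "E" else sxd).add(idx + 1)  # printed position
    chain = ProteinChain(f"synthetic-{cfg.seed}", "".join(letters))
    truth = ProteinTruth(frozenset(sxe), frozenset(sxd))
    # collision check: the scans must find exactly the planted sets
    assert scan_canonical(chain) == set(truth.sxe_positions)
    assert scan_sxd(chain) == set(truth.sxd_positions)
    return chain, truth


@dataclass(frozen=True)
class FamilyTruth:
    focal_matches: dict  # focal position -> number of records retaining ref residue


def gen_ortholog_family(
    cfg: SimulationConfig,
    reference: ProteinChain,
    focal_sites: Sequence[int] = (),
) -> tuple[Alignment, FamilyTruth]:
    """Gapless ortholog family with column-independent substitutions.

    The reference is record 0 and is never mutated; every other record
    substitutes each column independently with ``substitution_prob``.
    No phylogeny is modeled — sufficient for testing conservation
    arithmetic, not for emulating real evolutionary correlation.
    """
    if cfg.family_size < 2:
        raise ValueError("family_size must be >= 2")
    rng = cfg.rng()
    records = [(reference.id, reference.residues)]
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    for s in range(1, cfg.family_size):
        seq = list(reference.residues)
        for i in range(len(seq)):
            if rng.random() < cfg.substitution_prob:
                choices = [a for a in alphabet if a != seq[i]]
                seq[i] = choices[rng.integers(len(choices))]
        records.append((f"ortholog-{s}", "".join(seq)))
    aln = Alignment(tuple(records))
    focal = {
        pos: sum(
            1
            for _, seq in records
            if seq[pos - reference.numbering_offset]
            == reference.residues[pos - reference.numbering_offset]
        )
        for pos in focal_sites
    }
    return aln, FamilyTruth(focal)


@dataclass(frozen=True)
class PeakListTruth:
    true_k: dict  # m/z -> planted phosphate count (rung peaks only)
    noise_mzs: tuple


def gen_peaklist(cfg: SimulationConfig) -> tuple[list[Peak], PeakListTruth]:
    """Phospho-ladder rung peaks with mass noise plus spurious peaks.

    Rungs sit at base + k*Δp + N(0, σ) for each true count k; spurious
    peaks (Poisson number with the configured rate) are uniform over the
    ladder's mass range.
    """
    if cfg.mass_sigma < 0:
        raise ValueError("mass_sigma must be >= 0")
    rng = cfg.rng()
    dp = phospho_delta(cfg.mass_mode)
    peaks: list[Peak] = []
    true_k: dict = {}
    for k in cfg.true_phospho_counts:
        mz = cfg.base_mass + k * dp + rng.normal(0.0, cfg.mass_sigma)
        peaks.append(Peak(mz, intensity=float(rng.uniform(10, 100))))
        true_k[mz] = int(k)
    n_noise = int(rng.poisson(cfg.noise_peak_rate))
    k_hi = max(cfg.true_phospho_counts, default=0)
    lo, hi = cfg.base_mass - 50.0, cfg.base_mass + k_hi * dp + 50.0
    noise = []
    for _ in range(n_noise):
        # keep noise peaks off the rungs so truth stays unambiguous
        while True:
            mz = float(rng.uniform(lo, hi))
            if all(abs(mz - (cfg.base_mass + k * dp)) > 5.0 for k in range(k_hi + 2)):
                break
        peaks.append(Peak(mz, intensity=float(rng.uniform(1, 10))))
        noise.append(mz)
    order = rng.permutation(len(peaks))
    peaks = [peaks[i] for i in order]
    return peaks, PeakListTruth(true_k, tuple(noise))


@dataclass(frozen=True)
class EvidenceTruth:
    true_sites: frozenset  # resolved planted positions
    ambiguous_pairs: frozenset  # frozensets of 2 positions
    counts: dict  # site unit key (tuple) -> planted spectral count


def _overdispersed_counts(
    rng: np.random.Generator, n: int, mean: float, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts shifted to >= 1, mimicking spectral-count skew."""
    r = dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n) + 1


def gen_evidence_table(
    cfg: SimulationConfig, chain: ProteinChain
) -> tuple[list[PeptideEvidence], EvidenceTruth]:
    """Evidence rows over real tryptic peptides of the chain.

    True sites are drawn from the chain's S/T positions; each becomes one
    row on a tryptic peptide containing it, with an overdispersed
    spectral count.  With probability ``ambiguity_rate`` a site with
    another S/T in the same peptide is emitted as an either-or pair.
    """
    rng = cfg.rng()
    st_positions = [
        p for p in chain.positions() if chain.residue_at(p) in "ST"
    ]
    if cfg.n_true_sites > len(st_positions):
        raise ValueError(
            f"chain has only {len(st_positions)} S/T positions, "
            f"cannot plant {cfg.n_true_sites} sites"
        )
    chosen = sorted(
        rng.choice(st_positions, size=cfg.n_true_sites, replace=False).tolist()
    )
    peptides = [p for p in trypsin_digest(chain, TRYPSIN, max_missed=2) if len(p) >= 4]
    counts = _overdispersed_counts(
        rng, cfg.n_true_sites, cfg.count_mean, cfg.count_dispersion
    )
    rows: list[PeptideEvidence] = []
    resolved: set[int] = set()
    pairs: set[frozenset] = set()
    truth_counts: dict = {}
    for pos, count in zip(chosen, counts):
        covering = [p for p in peptides if p.start <= pos <= p.end]
        pep: Peptide = covering[rng.integers(len(covering))]
        unit = frozenset({pos})
        if rng.random() < cfg.ambiguity_rate:
            partners = [
                q
                for q in range(pep.start, pep.end + 1)
                if q != pos
                and pep.residues[q - pep.start] in "ST"
                and q not in chosen
            ]
            if partners:
                partner = int(partners[rng.integers(len(partners))])
                unit = frozenset({pos, partner})
        if len(unit) == 1:
            resolved.add(pos)
        else:
            pairs.add(unit)
        truth_counts[tuple(sorted(unit))] = int(count)
        rows.append(
            PeptideEvidence(
                residues=pep.residues,
                start=pep.start,
                end=pep.end,
                site_units=(unit,),
                spectral_count=int(count),
            )
        )
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    return rows, EvidenceTruth(frozenset(resolved), frozenset(pairs), truth_counts)
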