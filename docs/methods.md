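# Methods

## The problem and the pipeline

MEPE, a 508-residue intrinsically disordered SIBLING protein of bone and
teeth, is phosphorylated by the Golgi kinase FAM20C; the functional
weight falls on the C-terminal ASARM span (residues 489–508 in mature
numbering), whose nine serines control mineralization inhibition in a
phosphorylation-dependent way. The package reconstructs the
computational path from mass-spectrometric evidence to a residue-level
phosphosite map: construct modeling → tryptic digestion → theoretical
masses → MALDI phospho-ladder assignment → LC-MS/MS evidence collation →
motif classification → ortholog conservation.

## Coordinates and the construct

All analysis positions use mature-chain numbering, 1-based inclusive
(1–508); the 17-residue signal peptide is not part of analysis
numbering. The recombinant construct appends, in order, a KLGP linker,
the myc epitope EQKLISEEDL, an NSAVD linker and His6. Because the two
lysines removed in the protease-resistant mutant are conventionally
written K509A and K515A, printed numbering is continued through the tag
segments; the assembled coordinate table also records (segment name,
local index) for every residue, and tag serines are excluded from all
mature-chain site totals. The packaged construct fixture carries the
printed 489–508 tail as its base; runs over the full mature sequence
require the UniProt entry (Q9NQ76) and are deliberately outside the
offline path.

## Digestion

Trypsin specificity: cleave C-terminal to K/R unless the next residue is
P. Peptides are enumerated for 0..max_missed internal missed cleavages
(default 2, the usual database-search setting) as concatenations of
adjacent fully-cleaved fragments, sorted by start then length. Ragged
N-termini arise only through missed cleavages; semi-tryptic products are
not modeled. The mutation-effect report diffs cleavage-site sets of two
constructs, which is how K509A/K515A is seen to merge the tail into one
45-residue tryptic peptide.

## Masses

Residue masses come from the standard amino-acid compositions
(via pyteomics); the unit tests check the summation against an
independent atomic-composition oracle. A peptide's mass is the residue
sum plus one water, plus one proton (1.007276 Da) for MH⁺. Phosphate
adds 79.96633 Da (monoisotopic) or 79.9799 Da (average); oxidation
(M) and carbamidomethyl (C) are supported, though no packaged fixture
peptide contains Cys. MALDI comparisons use **average MH⁺**: the
reference value 4838.8 Da for the 45-mer is reproduced by the average
mass (4838.77) and not by the monoisotopic one (4836.06), settling
which convention the intact-mass figure uses. Ladders are
base + k·Δp, strictly increasing in k.

## Ladder assignment

Each observed peak is assigned the nearest rung k ≥ 0 of the ladder on
the unmodified MH⁺; a peak equidistant between rungs (within a 1e-9
relative epsilon, to keep the tie-break float-robust) takes the lower k —
conservative phosphate counting. Default tolerance is 0.1% of m/z
(≈5 Da at 5 kDa), suited to externally calibrated linear-mode MALDI
where observed-vs-theoretical gaps of 1.6–3.3 Da occur in the packaged
peak lists; tolerance can also be absolute in Da. Tightening the
tolerance can only lose assignments (tested property). An optional
intensity floor drops weak peaks; the default applies none, since the
packaged peak lists carry no intensities. The dephosphorylation control
passes iff the pre-treatment list shows some k > 0 and every assigned
post-treatment peak has k = 0.

## Motif rules

Scanned on serine by default (threonine by flag — the observed
phosphothreonines are not in S-x-E context, and motif analysis here
concerns serines):

- **S-x-E**: S at n, E at n+2.
- **S-x-pS**: smallest fixed point containing the S-x-E matches and any
  supplied phosphopositions, closed under "add S at n when n+2 is in the
  set". Monotone in the seed and idempotent at the fixed point.
- **S-x-D**: S at n, D at n+2.
- **Acidic context**: ≥1 of D/E at n+5..n+7, the generalized form of the
  SxQxxDEE-type motif. The literal strict motif (Q at n+2, all of
  n+5..n+7 acidic) is available via flags; the generalized default is
  used because the two sites this rule explains (S56, S436) do not match
  the literal pattern. Windows beyond the terminus simply cannot match.

## Collation and totals

An evidence row carries a peptide span, one unit per phosphate (a
resolved position, or an unordered either-or pair such as 103|104), a
spectral count, and expect/ppm metadata. Validation checks each claimed
site is S/T within its peptide (and the peptide against a parent
sequence when given); a bad row is rejected with its index. Aggregated
per-site spectral count is the **maximum** over rows containing the
site — printed counts are already cumulative over all peptides carrying
the site, so summing would double-count. Each ambiguous pair contributes
exactly one site everywhere, making Ser/Thr tallies ranges (20–21 / 1–2
on the packaged table). Major sites are those with aggregated count ≥ 20
(configurable); on the packaged table this threshold separates counts
{20, 30, 31, 39} from the next-highest count 7, yielding S43, S222,
S362, S441.

The MALDI merge is region-level: with ladder maximum k_max and t
phosphates attributed to tag serines, all region serines are marked
"assumed" phosphorylated when k_max − t ≥ (number of region serines);
otherwise the region is recorded as partially phosphorylated with no
site-level claim. On the fixtures: k_max = 10, t = 1 (the myc serine),
nine ASARM serines → all marked, grand total 22 + 9 = 31. Tag sites are
reported separately and never enter the grand total. The
without-kinase condition is carried as a second evidence set (the single
S43 row, the only site observed without FAM20C coexpression).

## Conservation

Reference positions are mapped to alignment columns by counting non-gap
reference characters; the inverse map is tested as a round trip.
Conservation is exact residue identity at the column (an aligned T does
not count for an S site; a gap counts as non-match), with the reference
included in the denominator: percent = round(100·k/N) half away from
zero. With N = 14 this reproduces the printed percent ladder
{100, 93, 86, 79, 71, 64, 57, 50, 43, 36, 29, 21} for k = 14..3; the
k/14 convention (rather than k/13) is what makes 93 = 13/14 rather than
an impossible k/13 value.

## Synthetic data

Generators are seeded through a single `numpy.random.Generator`; the
same seed reproduces every artifact bit-for-bit.

- **Proteins**: background drawn from an alphabet without S/T/D/E so the
  only S-x-E / S-x-D matches are the planted ones; anchors are spaced ≥5
  apart and the result is re-scanned as a collision check. Default 120
  residues with 4 S-x-E and 3 S-x-D plantings — the density of the real
  substrate's motif content at desk scale.
- **Ortholog families**: 14 records (the mammalian family size used for
  the real alignment), column-independent substitution at probability
  0.07 per non-reference residue (matching the ~90% typical per-site
  conservation of the real family). No phylogeny is modeled; this tests
  conservation arithmetic, not evolutionary realism.
- **Peak lists**: rungs at base + k·Δp + N(0, σ) with σ = 0.3 Da
  (sub-Da reproducibility of linear-mode peak positions), plus
  Poisson-count uniform noise peaks kept ≥5 Da off the rungs so the
  planted truth stays unambiguous.
- **Evidence tables**: true sites drawn from the chain's S/T positions,
  placed on real tryptic peptides; spectral counts from a shifted
  negative binomial (mean 8, dispersion 1.5 — skewed like real count
  columns: many 1–7, few ≥20); either-or ambiguity injected at a
  configurable rate by pairing with another S/T in the same peptide.

What passing synthetic tests do **not** show: behavior under correlated
evolution, real MALDI baseline/adduct structure, ionization bias, or
MS/MS localization error beyond the either-or model.

## Numerical and design choices

- Round-half-away for conservation percentages (Python's banker's
  rounding would map 50.0 differently on even/odd boundaries).
- Ladder tie-break to the lower k with a 1e-9 relative epsilon.
- Digestion order is deterministic (start, then length); collation is
  invariant to evidence row order and duplication (tested).
- The reproduction pipeline is fully deterministic; the acceptance
  script's seed only shuffles evidence rows before collation to exercise
  order invariance.

## Problem sizes

All packaged computations are desk-scale: one 45-residue peptide, a
23-row evidence table, two-peak and one-peak MALDI lists, and synthetic
chains of 40–200 residues with families of 14; property tests run
random sequences up to length 200 and peptide sets up to 50-mers. The
noisy-ladder recovery test spans 200 seeds of an 8-rung ladder.

## Known limitations

- The full 508-residue mature sequence is not packaged (it is not
  printed in the source material); full-sequence motif counts and the
  real 14-species conservation table require the optional UniProt inputs
  and are excluded from the offline path.
- Whether the real C-terminal peptide carries exactly two missed
  cleavages in the full construct depends on the residue preceding R489,
  which the packaged tail cannot determine.
- In the 45-mer, a direct scan finds three S-x-E serines (two ASARM, one
  myc); an external count of four Ser-x-Glu/pSer-conforming residues is
  not reproducible from the printed sequence alone, and no fourth site
  is hard-coded.
- Mascot expect values and ppm errors are carried as metadata only;
  no spectrum re-scoring or probabilistic site localization is done.
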