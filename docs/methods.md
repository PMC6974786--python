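# Methods

## Scope and model

`cliff3` identifies activity cliffs (ACs) from analog series (AS) with a
target-set-dependent potency-difference criterion. The unit of analysis is a
*target set*: all curated compounds with an assay-independent equilibrium
constant (pKi, −log₁₀ Ki in molar units) against one protein. The method has
no fitted parameters; everything is derived from the input structures and
potencies through the rules below.

## Data curation

Input rows are validated (parseable SMILES, finite potency), salts are
stripped by keeping the largest organic fragment (ties broken by canonical
SMILES), and structures are canonicalized with stereochemistry retained —
two stereoisomers are distinct compounds. Potencies may be given as pKi or
as Ki with a unit column (`nM`, `uM`, `M`; converted as pKi = 9 − log₁₀
Ki[nM] etc.). Replicate measurements for one (structure, target) aggregate
by arithmetic mean by default; a median policy and a
discard-if-range-exceeds(r) policy (default r = 1 log unit) are available.
pKi outside (0, 15) triggers a warning, not rejection. Rejected rows are
collected with line numbers and reasons, never silently dropped.

## Retrosynthetic bond table

Cleavable bonds are acyclic single bonds matching one of eleven classical
retrosynthetic bond-type patterns (amide, ester, amine, urea, ether, olefin,
quaternary N–C, aromatic N–aliphatic C, lactam N–aliphatic C, biaryl,
sulfonamide), expressed as two-atom SMARTS in a configuration table
(`cliff3.recap.DEFAULT_RECAP_RULES`, YAML-overridable). Notes:

- Patterns overlap chemically (a urea N–C(=O) bond also matches the amide
  pattern); the table order is a priority order and each bond receives the
  first matching rule id, so assignment is unique and deterministic.
- The olefin entry describes a C=C double bond; since only acyclic *single*
  bonds are cut, it can never fire. It stays in the table so the full
  classical rule set remains visible and editable.
- The ether pattern requires an oxygen bonded to two carbons, so phenols and
  alcohols are not cut; the amine pattern excludes amide, sulfonamide and
  imine nitrogens, which are owned by their own rules.

## Core/substituent enumeration

For every subset of 1–5 cleavable bonds (capped at 5000 subsets per
compound; a compound over the cap is skipped and logged), the bonds are cut
simultaneously. A subset is a valid split only when exactly one fragment —
the core — touches every cut bond (star topology; for single cuts both
fragments are candidate cores) and satisfies the size rule

    core heavy atoms ≥ 2 × Σ substituent heavy atoms   (non-strict).

Substituents are replaced by hydrogens to give the generalized core; splits
whose hydrogen-capped core fails sanitization are discarded and logged.

**Site identity.** Substitution sites are numbered by the canonical SMILES
output order of the core's attachment (dummy) atoms. Canonical ranking is a
graph invariant, so isomorphic cores from different compounds number their
sites compatibly, and rebuilding a compound by welding its substituents onto
a fresh parse of the core reproduces it exactly (tested for 100% of emitted
splits). Sites in one automorphism orbit ("symmetry class") are
interchangeable attachment points: substituent tuples are compared as
multisets within each class, and the differing-site count of a pair is the
minimum over within-class permutations. Permutations are taken freely within
an orbit rather than over the exact automorphism group — a deliberate
simplification that can in principle undercount differing sites on cores
with intertwined symmetric sites; no such core arises in the benchmarks.

## Analog series

Series identity is the canonical *attachment-annotated* core (dummy atoms at
the sites), not the bare hydrogen-generalized SMILES: a bare-core key would
merge positional isomers (ortho- vs para-substituted analogs) into one
series with clashing substituent tuples. The hydrogen-generalized core is
still computed and reported as the series' `core_smiles`.

A compound whose entire structure equals the generalized core joins the
series as the all-hydrogen member, which makes H→R analog pairs visible.
Partial-hydrogen membership in multi-site series (compound = core +
substituent at site 1 + H at site 2) is *not* discovered — it would require
matching every compound against every core under every hydrogen-capping of
its sites; this is a known limitation, and it only narrows multi-site series
membership, never corrupts it.

Each series with ≥ 2 members emits all n(n−1)/2 analog pairs. Because a
compound pair can be rediscovered through several cores, the per-target pair
collection is deduplicated by default (the representation with the fewest
differing sites wins; ties go to the larger core); a flag restores the raw
per-series enumeration.

## Statistics and threshold

- Quartiles: linear interpolation between order statistics (numpy's default
  convention); configurable (`quartile_mode`).
- IQR gate: sets with IQR ≥ `min_iqr` (default 1.0 log unit, inclusive
  boundary) proceed; each decision is logged.
- Threshold: `mean + 2σ` of the deduplicated pair ΔpKi distribution, with σ
  the *sample* standard deviation (n−1) by default (`sigma_mode:
  sample|population`). Sets with fewer than two pairs are excluded (σ
  undefined).
- Cliff comparison is non-strict (Δ ≥ threshold): an inclusive boundary
  avoids float-equality fragility at the threshold.

## Matched-pair (second-generation) mode

Single-cut splits index compounds by their single-cut cores; two compounds
sharing a core with different substituents form a matched molecular pair
(RMMP when cuts are restricted to the retrosynthetic table, MMP when any
acyclic single bond between heavy atoms may be cut). Size limits follow the
conventional choices and are configuration: substituent ≤ 13 heavy atoms,
core ≥ 2× substituent, exchanged-fragment size difference ≤ 8 heavy atoms.
With equal thresholds every RMMP cliff is also a third-generation
single-site cliff, since single-cut cores are a subset of the series cores
(asserted in the test suite).

## Dual-site decomposition

For a dual-site cliff with partners lo/hi differing at sites 1 and 2, the
hybrid "lo with site *i* swapped to hi's substituent" is welded, canonicalized
and looked up among the target set's structures (only same-target potencies
can contribute a Δᵢ = pKi(hybrid) − pKi(lo)). Classification, with Δdual the
cliff's potency difference, dominance fraction f = 0.8 and tolerance
τ = 0.5 pKi (both explicit configuration, since no standard numeric
convention exists):

1. any Δᵢ < 0 while Δdual > 0 → **both_contribute / compensatory** (a
   substitution working against the cliff takes precedence over dominance);
2. max(Δ₁, Δ₂) ≥ f·Δdual and min(Δ₁, Δ₂) < (1−f)·Δdual →
   **determined_by_one** (no effect label);
3. otherwise **both_contribute**, with effect **additive** if
   |Δ₁+Δ₂−Δdual| ≤ τ, **synergistic** if Δ₁+Δ₂ < Δdual−τ, **compensatory**
   if Δ₁+Δ₂ > Δdual+τ.

With exactly one measured hybrid, only dominance can be assessed: the
pattern is determined_by_one if that Δ ≥ f·Δdual, unclassified otherwise,
and no effect is assigned. Cliffs with three or more differing sites are
reported but not decomposed.

## Synthetic benchmarks

The generator assembles R-group enumerations on dummy-marked scaffolds by
the same welding machinery the decomposition uses, with an additive potency
model: pKi = baseline + Σ per-substituent increments (+ optional pairwise
interaction) + Gaussian noise. All randomness flows through one seeded
generator (one child stream per target); a given seed is byte-reproducible.

- **standard**: target FT1 — a 6×6 alkyl factorial (increments ≤ 0.3,
  noise σ = 0.05 pKi, baseline 6.0) on an 18-heavy-atom two-site scaffold,
  plus one planted tert-butyl-ether analog at +4.0 pKi, plus 40 pair-less
  fused-aromatic fillers spanning pKi 5–11. The fillers have no cleavable
  bonds, so they widen the compound distribution the IQR gate sees (IQR ≈ 2)
  without touching the analog-pair Δ distribution. The planted fraction
  (36/666 pairs) keeps planted Δ above mean+3σ while all distractor pairs
  stay below mean+1σ; the generator verifies both margins and refuses to
  emit a fixture that violates them. Target FT2 spans < 0.1 log units and
  exists to exercise the gate.
- **additive**: noise-free 6×6 factorial with one large substituent per
  site (+2.0, +2.2); every dual-site cliff has both hybrids measured and
  decomposes exactly additively.
- **dominant**: noise-free, with the strong (+3.8 = 95% of Δdual) and weak
  (+0.2) substituents entering through three extra compounds so the designed
  cliff has both hybrids measured while strong pairs stay rare enough not to
  inflate the threshold past the cliffs.
- **synergy**: the additive fixture plus a +1.5 interaction between the two
  large substituents.

What passing these benchmarks shows — and what it does not: the pipeline's
bookkeeping (series recovery, pair combinatorics, threshold arithmetic,
category assignment, hybrid lookup) is exact under an additive SAR with
modest noise. Real compound collections bring heterogeneous scaffolds,
correlated measurement error, non-additive SAR and curation noise that these
fixtures deliberately do not model; absolute cliff counts on real data are
therefore outside what the benchmarks can certify.

## Numerical and engineering choices

- All stage outputs are flat TSV/JSON with fixed float formatting (`%.9g`),
  stable sort orders and no timestamps; a run is byte-reproducible from its
  manifest.
- Quantities carried in pKi log units throughout; potency ordering within a
  pair breaks ties by compound id.
- Pathological inputs: fragmentation subsets that fail sanitization are
  dropped with a log entry; the 5000-subset cap bounds runtime on
  highly decorated molecules and is configurable.
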