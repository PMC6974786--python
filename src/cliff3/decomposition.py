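"""Decomposition of dual-site activity cliffs into single-site contributions.

A dual-site cliff's partners differ at two substitution sites. For each site,
a hybrid structure is built: the weaker compound with only that site's
substituent swapped to the stronger compound's. If the hybrid exists in the
target set (it has a measured pKi against the same target), the potency gain
attributable to that single substitution is Δi = pKi(hybrid) − pKi(weaker).
Comparing Δ1, Δ2 and the full cliff Δ classifies the pair: dominated by one
substitution, or jointly driven — and in the joint case additive, synergistic
(the whole exceeds the parts) or compensatory (one substitution works against
the other).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping

from .analog_series import count_differing_sites
from .chem import canonical_smiles, weld
from .cliff_detection import ActivityCliff

logger = logging.getLogger(__name__)

__all__ = [
    "SingleSiteAnalogMatch",
    "EffectClassification",
    "find_single_site_analogs",
    "classify_contribution",
    "structure_index",
]

Pattern = Literal["determined_by_one", "both_contribute", "unclassified"]
Effect = Literal["additive", "synergistic", "compensatory"]


@dataclass(frozen=True)
class SingleSiteAnalogMatch:
    site_index: int            # 1-based, over the pair's differing sites
    analog_id: str
    analog_pki: float
    delta_single: float        # analog_pki − pki_lo of the cliff


@dataclass(frozen=True)
class EffectClassification:
    matches_found: int
    pattern: Pattern
    effect: Effect | None
    dominance_fraction: float
    tolerance: float


def structure_index(compounds) -> dict[str, tuple[str, float]]:
    """canonical SMILES → (compound_id, pKi) lookup for hybrid search."""
    return {c.canonical_smiles: (c.compound_id, c.pki) for c in compounds}


def _differing_positions(cliff: ActivityCliff) -> list[int]:
    pair = cliff.pair
    return [
        i
        for i, (lo, hi) in enumerate(zip(pair.substituents_lo, pair.substituents_hi))
        if lo != hi
    ]


def find_single_site_analogs(
    dual_cliff: ActivityCliff,
    structures: Mapping[str, tuple[str, float]],
) -> list[SingleSiteAnalogMatch]:
    """Look up both single-substitution hybrids of a dual-site cliff.

    For site *i* of the two differing sites, the hybrid is the low-potency
    partner with that site's substituent replaced by the high-potency
    partner's. Hybrids that cannot be assembled chemically are reported as
    unmatched (logged); hybrids absent from ``structures`` simply yield no
    match.
    """
    pair = dual_cliff.pair
    if pair.differing_sites != 2:
        raise ValueError("decomposition applies to dual-site cliffs only")
    positions = _differing_positions(dual_cliff)
    if len(positions) != 2:
        # substituent tuples can differ at aligned positions that symmetry
        # renders equivalent; such pairs are not decomposable site-by-site
        logger.info(
            "cliff %s/%s: aligned tuples differ at %d positions, expected 2; skipped",
            pair.compound_lo, pair.compound_hi, len(positions),
        )
        return []
    matches: list[SingleSiteAnalogMatch] = []
    for site_number, pos in enumerate(positions, start=1):
        hybrid_subs = list(pair.substituents_lo)
        hybrid_subs[pos] = pair.substituents_hi[pos]
        mol = weld(pair.site_core_smiles, hybrid_subs)
        if mol is None:
            logger.info(
                "cliff %s/%s site %d: hybrid not chemically assemblable",
                pair.compound_lo, pair.compound_hi, site_number,
            )
            continue
        smiles = canonical_smiles(mol)
        found = structures.get(smiles)
        if found is None:
            continue
        analog_id, analog_pki = found
        if analog_id in (pair.compound_lo, pair.compound_hi):
            continue
        matches.append(
            SingleSiteAnalogMatch(site_number, analog_id, analog_pki,
                                  analog_pki - pair.pki_lo)
        )
    return matches


def classify_contribution(
    dual_cliff: ActivityCliff,
    matches: list[SingleSiteAnalogMatch],
    dominance_fraction: float = 0.8,
    tolerance: float = 0.5,
) -> EffectClassification:
    """Classify how two substitutions produce a dual-site cliff.

    With Δdual the cliff's potency difference and Δi the single-substitution
    gains: the pair is ``determined_by_one`` when the larger Δi covers at
    least ``dominance_fraction`` of Δdual while the smaller stays below the
    complementary fraction; otherwise, with both hybrids measured, both
    substitutions contribute, and the effect is additive when Δ1 + Δ2 matches
    Δdual within ``tolerance``, synergistic when the sum falls short of Δdual
    by more than the tolerance, and compensatory when a Δi is negative while
    Δdual is positive, or the sum overshoots Δdual beyond the tolerance.

    With a single measured hybrid, only dominance can be assessed: the pair
    is ``determined_by_one`` if that Δ covers the dominant fraction, and
    ``unclassified`` otherwise; the effect requires both hybrids.
    """
    delta_dual = dual_cliff.pair.delta_pki
    deltas = [m.delta_single for m in matches]
    if not matches:
        return EffectClassification(0, "unclassified", None, dominance_fraction, tolerance)
    if len(matches) == 1:
        pattern: Pattern = (
            "determined_by_one"
            if deltas[0] >= dominance_fraction * delta_dual
            else "unclassified"
        )
        return EffectClassification(1, pattern, None, dominance_fraction, tolerance)

    d_hi, d_lo = max(deltas), min(deltas)
    if d_lo < 0.0 < delta_dual:
        # a substitution that works against the cliff is a compensatory pair,
        # even though the dominance inequalities formally hold
        return EffectClassification(2, "both_contribute", "compensatory",
                                    dominance_fraction, tolerance)
    if d_hi >= dominance_fraction * delta_dual and d_lo < (1.0 - dominance_fraction) * delta_dual:
        # one substitution explains the cliff; the joint-effect labels
        # characterize pairs where both substitutions matter
        return EffectClassification(2, "determined_by_one", None,
                                    dominance_fraction, tolerance)
    pattern = "both_contribute"

    total = sum(deltas)
    if d_lo < 0.0 < delta_dual:
        effect: Effect = "compensatory"
    elif abs(total - delta_dual) <= tolerance:
        effect = "additive"
    elif total < delta_dual - tolerance:
        effect = "synergistic"
    else:
        effect = "compensatory"
    return EffectClassification(2, pattern, effect, dominance_fraction, tolerance)
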