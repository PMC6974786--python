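"""Activity-cliff calling.

Third-generation cliffs: analog pairs from the series machinery whose ΔpKi
reaches the target-set-dependent threshold (pair-Δ mean + 2σ), categorized by
their number of differing substitution sites. Second-generation mode calls
matched-molecular-pair cliffs instead: pairs differing by one substituent
exchange at a single cut site, with the cut restricted to retrosynthetic bond
types (RMMP) or allowed on any acyclic single bond (MMP), under conventional
substituent size limits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from rdkit import Chem

from .activity_data import TargetSet
from .analog_series import AnalogPair
from .chem import parse_smiles
from .fragmentation import CoreSplit, _split_from_subset
from .potency_stats import TargetSetStats
from .recap import DEFAULT_RECAP_RULES, CleavableBond, RecapRule, find_cleavable_bonds

__all__ = ["ActivityCliff", "MmpSizeLimits", "detect_cliffs", "detect_rmmp_cliffs",
           "single_cut_splits"]

GenerationMode = Literal["third", "second_rmmp", "second_mmp"]


@dataclass(frozen=True)
class ActivityCliff:
    pair: AnalogPair
    target_id: str
    category: Literal["single_site", "multi_site"]
    site_count_of_pair: int
    threshold_used: float
    generation_mode: GenerationMode


@dataclass(frozen=True)
class MmpSizeLimits:
    """Conventional size restrictions for matched-molecular-pair substituents."""

    max_substituent_heavy_atoms: int = 13
    min_core_to_substituent_ratio: float = 2.0
    max_exchange_size_difference: int = 8


def _make_cliff(
    pair: AnalogPair, threshold: float, mode: GenerationMode
) -> ActivityCliff:
    return ActivityCliff(
        pair=pair,
        target_id=pair.target_id,
        category="single_site" if pair.differing_sites == 1 else "multi_site",
        site_count_of_pair=pair.differing_sites,
        threshold_used=threshold,
        generation_mode=mode,
    )


def detect_cliffs(
    pairs: Iterable[AnalogPair],
    stats: TargetSetStats,
    strict: bool = False,
) -> list[ActivityCliff]:
    """Third-generation cliffs: pairs at or above the set's ΔpKi threshold.

    The comparison is non-strict by default (Δ equal to the threshold
    qualifies). Output is ordered by descending ΔpKi, then compound ids.
    """
    if stats.threshold is None:
        raise ValueError(f"target set {stats.target_id}: threshold not computed")
    threshold = stats.threshold
    hit = (
        (lambda d: d > threshold) if strict else (lambda d: d >= threshold)
    )
    cliffs = [
        _make_cliff(p, threshold, "third") for p in pairs if hit(p.delta_pki)
    ]
    cliffs.sort(key=lambda c: (-c.pair.delta_pki, c.pair.compound_lo, c.pair.compound_hi))
    return cliffs


_ANY_SINGLE_BOND_RULE = "any_single_bond"


def _all_acyclic_single_bonds(mol: Chem.Mol) -> list[CleavableBond]:
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if mol.GetAtomWithIdx(a).GetAtomicNum() <= 1 or mol.GetAtomWithIdx(b).GetAtomicNum() <= 1:
            continue
        out.append(CleavableBond(min(a, b), max(a, b), _ANY_SINGLE_BOND_RULE))
    return sorted(out)


def single_cut_splits(
    mol: Chem.Mol,
    restrict_to_recap: bool,
    limits: MmpSizeLimits,
    rules: tuple[RecapRule, ...] = DEFAULT_RECAP_RULES,
) -> list[CoreSplit]:
    """Single-bond core/substituent splits for matched-pair indexing.

    ``restrict_to_recap`` selects retrosynthetic cuts (RMMP) versus all
    acyclic single bonds between heavy atoms (MMP). The core/substituent size
    ratio and the absolute substituent size cap are enforced here; the
    exchange size difference is a pair-level check.
    """
    bonds = (
        find_cleavable_bonds(mol, rules)
        if restrict_to_recap
        else _all_acyclic_single_bonds(mol)
    )
    splits: list[CoreSplit] = []
    for bond in bonds:
        for split in _split_from_subset(mol, (bond,)):
            if split.substituent_heavy_atoms > limits.max_substituent_heavy_atoms:
                continue
            if split.core_heavy_atoms < (
                limits.min_core_to_substituent_ratio * split.substituent_heavy_atoms
            ):
                continue
            splits.append(split)
    # distinct splits only (symmetric bonds can duplicate)
    seen: set[tuple] = set()
    unique = []
    for split in sorted(splits, key=CoreSplit.sort_key):
        key = (split.site_core_smiles, split.substituents)
        if key not in seen:
            seen.add(key)
            unique.append(split)
    return unique


def detect_rmmp_cliffs(
    target_set: TargetSet,
    stats: TargetSetStats,
    size_limits: MmpSizeLimits = MmpSizeLimits(),
    restrict_to_recap: bool = True,
    rules: tuple[RecapRule, ...] = DEFAULT_RECAP_RULES,
    strict: bool = False,
    precomputed_splits: dict[str, Sequence[CoreSplit]] | None = None,
) -> list[ActivityCliff]:
    """Second-generation matched-pair cliffs of one target set.

    Compounds sharing a single-cut core with different substituents form a
    matched pair; those whose ΔpKi reaches ``stats.threshold`` are cliffs
    (mode ``second_rmmp``, or ``second_mmp`` when cuts are unrestricted).
    """
    if stats.threshold is None:
        raise ValueError(f"target set {stats.target_id}: threshold not computed")
    mode: GenerationMode = "second_rmmp" if restrict_to_recap else "second_mmp"

    index: dict[str, list[tuple[str, float, CoreSplit]]] = {}
    for compound in target_set.compounds:
        if precomputed_splits is not None and compound.compound_id in precomputed_splits:
            splits = list(precomputed_splits[compound.compound_id])
        else:
            mol = parse_smiles(compound.canonical_smiles)
            if mol is None:
                continue
            splits = single_cut_splits(mol, restrict_to_recap, size_limits, rules)
        for split in splits:
            index.setdefault(split.site_core_smiles, []).append(
                (compound.compound_id, compound.pki, split)
            )

    threshold = stats.threshold
    hit = (lambda d: d > threshold) if strict else (lambda d: d >= threshold)
    best: dict[tuple[str, str], AnalogPair] = {}
    for site_core in sorted(index):
        entries = index[site_core]
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                (id_a, pki_a, sp_a), (id_b, pki_b, sp_b) = entries[i], entries[j]
                if id_a == id_b or sp_a.substituents == sp_b.substituents:
                    continue
                size_diff = abs(
                    sp_a.substituent_heavy_atoms - sp_b.substituent_heavy_atoms
                )
                if size_diff > size_limits.max_exchange_size_difference:
                    continue
                if (pki_a, id_a) > (pki_b, id_b):
                    id_a, pki_a, sp_a, id_b, pki_b, sp_b = id_b, pki_b, sp_b, id_a, pki_a, sp_a
                pair = AnalogPair(
                    target_id=target_set.target_id,
                    site_core_smiles=site_core,
                    core_smiles=sp_a.core_smiles,
                    core_heavy_atoms=sp_a.core_heavy_atoms,
                    compound_lo=id_a,
                    compound_hi=id_b,
                    pki_lo=pki_a,
                    pki_hi=pki_b,
                    substituents_lo=sp_a.substituents,
                    substituents_hi=sp_b.substituents,
                    site_count=1,
                    site_classes=sp_a.site_classes,
                    differing_sites=1,
                )
                cur = best.get(pair.key)
                if cur is None or pair.core_heavy_atoms > cur.core_heavy_atoms:
                    best[pair.key] = pair
    cliffs = [
        _make_cliff(p, threshold, mode)
        for p in (best[k] for k in sorted(best))
        if hit(p.delta_pki)
    ]
    cliffs.sort(key=lambda c: (-c.pair.delta_pki, c.pair.compound_lo, c.pair.compound_hi))
    return cliffs
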