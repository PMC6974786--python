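"""Core–substituent enumeration by systematic retrosynthetic fragmentation.

For each compound, every subset of 1–5 cleavable bonds is cut simultaneously.
A subset is a valid split only when exactly one resulting fragment — the core
— is incident to *all* cut bonds (star topology: each other fragment is then a
substituent hanging off the core at one site) and the core carries at least
twice as many heavy atoms as all substituents combined. Substituents are then
replaced by hydrogens to produce the generalized core.

Site bookkeeping: a core's substitution sites are numbered by the canonical
SMILES output order of its attachment (dummy) atoms, which is a graph
invariant — isomorphic cores coming from different compounds number their
sites compatibly, so substituent tuples can be compared position by position
(up to permutation within topologically equivalent sites).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

from rdkit import Chem

from .chem import (
    canonical_smiles,
    clear_dummy_labels,
    dummy_output_positions,
    heavy_atom_count,
    remove_dummies_with_h,
    site_symmetry_classes,
)
from .recap import DEFAULT_RECAP_RULES, CleavableBond, RecapRule, find_cleavable_bonds

logger = logging.getLogger(__name__)

__all__ = ["CoreSplit", "enumerate_core_splits", "generalize_core",
           "DEFAULT_SUBSET_CAP", "MAX_SITES"]

MAX_SITES = 5
DEFAULT_SUBSET_CAP = 5000


@dataclass(frozen=True)
class CoreSplit:
    """One core/substituent decomposition of a compound.

    ``site_core_smiles`` is the canonical core with a dummy atom at every
    substitution site (the series identity); ``core_smiles`` is the
    hydrogen-generalized form. ``substituents[i]`` sits at site *i* (canonical
    dummy order of ``site_core_smiles``); ``sites[i]`` records the rule that
    cut it. ``site_classes[i]`` is the symmetry orbit of site *i* — sites in
    one orbit are interchangeable attachment points.
    """

    core_smiles: str
    site_core_smiles: str
    site_count: int
    sites: tuple[str, ...]            # recap rule id per site
    site_classes: tuple[int, ...]
    substituents: tuple[str, ...]     # canonical single-dummy fragment SMILES
    core_heavy_atoms: int
    substituent_heavy_atoms: int

    def sort_key(self) -> tuple:
        return (self.site_count, self.site_core_smiles, self.substituents)


def generalize_core(core_with_attachment_points: Chem.Mol) -> str | None:
    """Replace every attachment marker by hydrogen and canonicalize.

    Returns None when hydrogen substitution produces an unsanitizable
    structure (the caller discards and logs the split).
    """
    capped = remove_dummies_with_h(core_with_attachment_points)
    if capped is None:
        return None
    return canonical_smiles(capped)


def _split_from_subset(
    mol: Chem.Mol, subset: tuple[CleavableBond, ...]
) -> list[CoreSplit]:
    """Build the valid CoreSplits (0, 1, or — for single cuts — up to 2)
    obtainable from cutting one bond subset."""
    bond_indices = [
        mol.GetBondBetweenAtoms(cb.atom_index_a, cb.atom_index_b).GetIdx()
        for cb in subset
    ]
    k = len(subset)
    try:
        fragmented = Chem.FragmentOnBonds(
            mol,
            bond_indices,
            addDummies=True,
            dummyLabels=[(i + 1, i + 1) for i in range(k)],
        )
        pieces = Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=True)
    except (Chem.AtomValenceException, Chem.KekulizeException, RuntimeError, ValueError):
        logger.info("discarding subset %s: fragmentation failed sanitization", subset)
        return []
    if len(pieces) != k + 1:
        # Should not happen for acyclic bonds; guard against surprises.
        return []

    def labels(piece: Chem.Mol) -> frozenset[int]:
        return frozenset(
            a.GetIsotope() for a in piece.GetAtoms() if a.GetAtomicNum() == 0
        )

    all_labels = frozenset(range(1, k + 1))
    core_candidates = [p for p in pieces if labels(p) == all_labels]

    splits = []
    for core in core_candidates:
        subs = [p for p in pieces if p is not core]
        sub_heavy = sum(heavy_atom_count(p) for p in subs)
        core_heavy = heavy_atom_count(core)
        if core_heavy < 2 * sub_heavy:
            continue
        cleared = clear_dummy_labels(core)
        site_core, dummy_idx = dummy_output_positions(cleared)
        classes = site_symmetry_classes(cleared, dummy_idx)
        generalized = generalize_core(core)
        if generalized is None:
            logger.info("discarding split of %s: H-capping failed", Chem.MolToSmiles(mol))
            continue
        # cut label of each dummy, in canonical site order
        site_labels = [core.GetAtomWithIdx(i).GetIsotope() for i in dummy_idx]
        sub_by_label = {next(iter(labels(p))): p for p in subs}
        substituents = tuple(
            canonical_smiles(clear_dummy_labels(sub_by_label[lab])) for lab in site_labels
        )
        rule_by_label = {i + 1: cb.recap_rule_id for i, cb in enumerate(subset)}
        rules = tuple(rule_by_label[lab] for lab in site_labels)
        splits.append(
            CoreSplit(
                core_smiles=generalized,
                site_core_smiles=site_core,
                site_count=k,
                sites=rules,
                site_classes=classes,
                substituents=substituents,
                core_heavy_atoms=core_heavy,
                substituent_heavy_atoms=sub_heavy,
            )
        )
    return splits


def _normalized_identity(split: CoreSplit) -> tuple:
    """Split identity with substituents sorted inside each symmetry orbit
    (two splits equal up to swapping equivalent sites are one split)."""
    by_class: dict[int, list[str]] = {}
    for cls, sub in zip(split.site_classes, split.substituents):
        by_class.setdefault(cls, []).append(sub)
    canon = tuple(
        (cls, tuple(sorted(subs))) for cls, subs in sorted(by_class.items())
    )
    return (split.site_core_smiles, canon)


def enumerate_core_splits(
    mol: Chem.Mol,
    max_sites: int = MAX_SITES,
    rules: tuple[RecapRule, ...] = DEFAULT_RECAP_RULES,
    subset_cap: int = DEFAULT_SUBSET_CAP,
    cleavable: list[CleavableBond] | None = None,
) -> list[CoreSplit]:
    """Enumerate all valid core/substituent splits of one compound.

    Returns splits in deterministic order (site count, then canonical core,
    then substituent tuple). Raises :class:`CombinatorialCapExceeded` when the
    number of bond subsets passes ``subset_cap``; callers skip the compound
    and log it.
    """
    if cleavable is None:
        cleavable = find_cleavable_bonds(mol, rules)
    n = len(cleavable)
    total_subsets = 0
    seen: set[tuple] = set()
    out: list[CoreSplit] = []
    for k in range(1, min(max_sites, n) + 1):
        for subset in combinations(cleavable, k):
            total_subsets += 1
            if total_subsets > subset_cap:
                raise CombinatorialCapExceeded(
                    f"{total_subsets} bond subsets exceed cap {subset_cap}"
                )
            for split in _split_from_subset(mol, subset):
                ident = _normalized_identity(split)
                if ident not in seen:
                    seen.add(ident)
                    out.append(split)
    out.sort(key=CoreSplit.sort_key)
    return out


class CombinatorialCapExceeded(RuntimeError):
    """A compound produced more fragmentation subsets than the configured cap."""
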