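"""Analog-series construction and analog-pair enumeration.

An analog series collects every compound of one target set that decomposes
onto the same substitution-annotated core. Series identity is the canonical
core *with attachment points marked*: hydrogen-generalizing alone would merge
positional isomers (an ortho- and a para-substituted analog share the bare
core but are not substituent-exchange analogs of each other). The
hydrogen-generalized core is still carried along as the reported core form,
and a compound whose whole structure equals that generalized core joins the
series as the all-hydrogen member, which is what makes H→R pairs visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .activity_data import TargetSet
from .chem import H_SUBSTITUENT
from .fragmentation import CoreSplit

logger = logging.getLogger(__name__)

__all__ = [
    "SeriesMember",
    "AnalogSeries",
    "AnalogPair",
    "build_series",
    "enumerate_pairs",
    "deduplicate_pairs",
    "count_differing_sites",
]


@dataclass(frozen=True)
class SeriesMember:
    compound_id: str
    substituents: tuple[str, ...]  # aligned to series sites
    pki: float


@dataclass(frozen=True)
class AnalogSeries:
    target_id: str
    site_core_smiles: str          # canonical core with dummy attachment atoms
    core_smiles: str               # hydrogen-generalized core
    site_count: int
    site_classes: tuple[int, ...]  # symmetry orbit per site
    core_heavy_atoms: int
    members: tuple[SeriesMember, ...]

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class AnalogPair:
    """Two members of one series, ordered by potency (lo ≤ hi)."""

    target_id: str
    site_core_smiles: str
    core_smiles: str
    core_heavy_atoms: int
    compound_lo: str
    compound_hi: str
    pki_lo: float
    pki_hi: float
    substituents_lo: tuple[str, ...]
    substituents_hi: tuple[str, ...]
    site_count: int
    site_classes: tuple[int, ...]
    differing_sites: int

    @property
    def delta_pki(self) -> float:
        return self.pki_hi - self.pki_lo

    @property
    def key(self) -> tuple[str, str]:
        """Unordered structural-pair identity within a target set."""
        return tuple(sorted((self.compound_lo, self.compound_hi)))  # type: ignore[return-value]


def count_differing_sites(
    a: Sequence[str], b: Sequence[str], site_classes: Sequence[int]
) -> int:
    """Number of substitution sites at which two aligned tuples differ.

    Sites sharing a symmetry class are interchangeable attachment points, so
    within each class only the multiset of substituents matters: the count is
    minimized over within-class permutations.
    """
    if not (len(a) == len(b) == len(site_classes)):
        raise ValueError("substituent tuples and site classes must align")
    differing = 0
    for cls in set(site_classes):
        idx = [i for i, c in enumerate(site_classes) if c == cls]
        if len(idx) == 1:
            differing += a[idx[0]] != b[idx[0]]
            continue
        pool = [b[i] for i in idx]
        for i in idx:
            if a[i] in pool:
                pool.remove(a[i])
            else:
                differing += 1
    return differing


def _normalized_tuple(
    substituents: Sequence[str], site_classes: Sequence[int]
) -> tuple[str, ...]:
    """Sort substituents within each symmetry class (duplicate detection)."""
    out = list(substituents)
    for cls in set(site_classes):
        idx = [i for i, c in enumerate(site_classes) if c == cls]
        for i, sub in zip(idx, sorted(out[i] for i in idx)):
            out[i] = sub
    return tuple(out)


def build_series(
    target_set: TargetSet,
    core_splits: Mapping[str, Sequence[CoreSplit]],
    min_members: int = 2,
) -> list[AnalogSeries]:
    """Group one target set's compounds into analog series.

    ``core_splits`` maps compound id → its enumerated splits. A compound
    appears in every series whose core it produces; a compound identical to a
    series' generalized core joins as the all-hydrogen member. Series with
    fewer than ``min_members`` members are dropped. Output order is
    deterministic (site count, canonical core).
    """
    by_core: dict[str, dict] = {}
    pki = {c.compound_id: c.pki for c in target_set.compounds}
    by_structure = {c.canonical_smiles: c.compound_id for c in target_set.compounds}

    for compound in target_set.compounds:
        for split in core_splits.get(compound.compound_id, ()):
            entry = by_core.setdefault(
                split.site_core_smiles,
                {
                    "core_smiles": split.core_smiles,
                    "site_count": split.site_count,
                    "site_classes": split.site_classes,
                    "core_heavy_atoms": split.core_heavy_atoms,
                    "members": {},
                },
            )
            norm = _normalized_tuple(split.substituents, split.site_classes)
            prior = entry["members"].get(compound.compound_id)
            if prior is None:
                entry["members"][compound.compound_id] = split.substituents
            # a compound can reach the same core via several bond subsets;
            # the aligned tuple is identical up to symmetry, keep the first

    series_out: list[AnalogSeries] = []
    for site_core in sorted(by_core, key=lambda c: (by_core[c]["site_count"], c)):
        entry = by_core[site_core]
        members = {
            cid: subs for cid, subs in entry["members"].items()
        }
        # all-hydrogen member: the bare generalized core, when present in the set
        bare_id = by_structure.get(entry["core_smiles"])
        if bare_id is not None and bare_id not in members:
            members[bare_id] = (H_SUBSTITUENT,) * entry["site_count"]

        # duplicate substituent tuples would mean duplicate structures
        seen: dict[tuple[str, ...], str] = {}
        kept: dict[str, tuple[str, ...]] = {}
        for cid in sorted(members):
            norm = _normalized_tuple(members[cid], entry["site_classes"])
            if norm in seen:
                logger.warning(
                    "series %s: %s and %s share a substituent tuple; keeping %s",
                    site_core, seen[norm], cid, seen[norm],
                )
                continue
            seen[norm] = cid
            kept[cid] = members[cid]
        if len(kept) < min_members:
            continue
        series_out.append(
            AnalogSeries(
                target_id=target_set.target_id,
                site_core_smiles=site_core,
                core_smiles=entry["core_smiles"],
                site_count=entry["site_count"],
                site_classes=entry["site_classes"],
                core_heavy_atoms=entry["core_heavy_atoms"],
                members=tuple(
                    SeriesMember(cid, kept[cid], pki[cid]) for cid in sorted(kept)
                ),
            )
        )
    return series_out


def enumerate_pairs(series: AnalogSeries) -> list[AnalogPair]:
    """All n·(n−1)/2 analog pairs of one series, potency-ordered."""
    pairs: list[AnalogPair] = []
    members = series.members
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            a, b = members[i], members[j]
            if (a.pki, a.compound_id) > (b.pki, b.compound_id):
                a, b = b, a
            pairs.append(
                AnalogPair(
                    target_id=series.target_id,
                    site_core_smiles=series.site_core_smiles,
                    core_smiles=series.core_smiles,
                    core_heavy_atoms=series.core_heavy_atoms,
                    compound_lo=a.compound_id,
                    compound_hi=b.compound_id,
                    pki_lo=a.pki,
                    pki_hi=b.pki,
                    substituents_lo=a.substituents,
                    substituents_hi=b.substituents,
                    site_count=series.site_count,
                    site_classes=series.site_classes,
                    differing_sites=count_differing_sites(
                        a.substituents, b.substituents, series.site_classes
                    ),
                )
            )
    return pairs


def deduplicate_pairs(pairs: Iterable[AnalogPair]) -> list[AnalogPair]:
    """Collapse the same structural pair seen through several cores.

    The representation with the fewest differing sites wins; ties go to the
    larger core. Returns pairs sorted by compound ids.
    """
    best: dict[tuple[str, str], AnalogPair] = {}
    for pair in pairs:
        cur = best.get(pair.key)
        if cur is None or (
            (pair.differing_sites, -pair.core_heavy_atoms, pair.site_core_smiles)
            < (cur.differing_sites, -cur.core_heavy_atoms, cur.site_core_smiles)
        ):
            best[pair.key] = pair
    return [best[k] for k in sorted(best)]
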