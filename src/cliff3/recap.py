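"""Retrosynthetic (RECAP-style) cleavable-bond perception.

The eleven classical retrosynthetic bond types are expressed as two-atom
SMARTS patterns joined by an acyclic single bond. The table is configuration,
not code: pass a custom rule list to :func:`find_cleavable_bonds` or load one
from YAML with :func:`load_rules`. Patterns may overlap chemically (a urea
N–C(=O) bond also looks like an amide); the table order is a priority order
and each bond is assigned to the first rule that matches it, so every
:class:`CleavableBond` carries exactly one rule id.

The olefin entry is a double-bond type and therefore can never satisfy the
acyclic-single-bond requirement enforced here; it is kept in the table so the
rule set mirrors the full classical list and stays editable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml
from rdkit import Chem

__all__ = ["RecapRule", "CleavableBond", "DEFAULT_RECAP_RULES", "load_rules",
           "find_cleavable_bonds"]


@dataclass(frozen=True)
class RecapRule:
    """One retrosynthetic bond type: an identifier plus a two-atom SMARTS."""

    rule_id: str
    smarts: str

    def pattern(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS for rule {self.rule_id!r}: {self.smarts!r}")
        return patt


DEFAULT_RECAP_RULES: tuple[RecapRule, ...] = (
    RecapRule("urea", "[NX3;$(N[CX3](=O)[NX3])]-!@[CX3;$(C(=O)([NX3])[NX3])]"),
    RecapRule("amide", "[CX3;$(C=O)]-!@[NX3;!$(N=*)]"),
    RecapRule("sulfonamide", "[SX4;$(S(=O)(=O))]-!@[NX3]"),
    RecapRule("ester", "[CX3;$(C=O)]-!@[OX2;$(O[#6])]"),
    RecapRule("lactam_n_aliphatic_c", "[NX3;R;$([NX3;R]@[CX3]=O)]-!@[CX4]"),
    RecapRule("quaternary_n", "[NX4+]-!@[#6]"),
    RecapRule("aromatic_n_aliphatic_c", "[n]-!@[CX4]"),
    RecapRule("amine", "[NX3;!$(N=*);!$(N[CX3]=[O,S,N]);!$(N[SX4](=O)=O)]-!@[CX4]"),
    RecapRule("ether", "[#6;!$([CX3]=O)]-!@[OX2;$(O([#6])[#6]);!$(O[CX3]=[OX1])]"),
    RecapRule("olefin", "[CX3]=!@[CX3]"),
    RecapRule("biaryl", "[c]-!@[c]"),
)


def load_rules(path: str | Path) -> tuple[RecapRule, ...]:
    """Load a rule table from a YAML list of ``{rule_id, smarts}`` mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"{path}: expected a non-empty list of rules")
    rules = tuple(RecapRule(str(r["rule_id"]), str(r["smarts"])) for r in raw)
    for rule in rules:
        rule.pattern()  # validate eagerly
    return rules


@dataclass(frozen=True, order=True)
class CleavableBond:
    """An acyclic single bond matched by one retrosynthetic rule.

    Atom indices refer to the canonical compound molecule and are stored
    sorted, so the natural ordering of the dataclass gives the deterministic
    enumeration order.
    """

    atom_index_a: int
    atom_index_b: int
    recap_rule_id: str


def find_cleavable_bonds(
    mol: Chem.Mol, rules: tuple[RecapRule, ...] = DEFAULT_RECAP_RULES
) -> list[CleavableBond]:
    """All acyclic single bonds of ``mol`` matching a retrosynthetic rule.

    Each bond is reported once, labeled with the first matching rule in table
    order; results are sorted by atom-index pair.
    """
    assigned: dict[tuple[int, int], str] = {}
    for rule in rules:
        patt = rule.pattern()
        for match in mol.GetSubstructMatches(patt):
            a, b = match[0], match[1]
            bond = mol.GetBondBetweenAtoms(a, b)
            if bond is None or bond.GetBondType() != Chem.BondType.SINGLE:
                continue
            if bond.IsInRing():
                continue
            key = (min(a, b), max(a, b))
            assigned.setdefault(key, rule.rule_id)
    return sorted(
        CleavableBond(a, b, rid) for (a, b), rid in assigned.items()
    )
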