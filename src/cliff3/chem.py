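"""Shared RDKit helpers: parsing, salt stripping, canonicalization, welding.

All structure handling in the package funnels through these functions so that
canonical forms are produced identically everywhere (same RDKit options, same
salt-stripping policy).
"""

from __future__ import annotations

from rdkit import Chem
from rdkit import RDLogger

# RDKit is chatty about kekulization on fragments; warnings are handled as
# explicit discard-and-log decisions in the fragmentation code instead.
RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "parse_smiles",
    "strip_salts",
    "canonical_smiles",
    "heavy_atom_count",
    "clear_dummy_labels",
    "dummy_output_positions",
    "site_symmetry_classes",
    "remove_dummies_with_h",
    "weld",
    "H_SUBSTITUENT",
]


def parse_smiles(smiles: str) -> Chem.Mol | None:
    """Parse a SMILES string; return None on failure instead of raising."""
    return Chem.MolFromSmiles(smiles)


def strip_salts(mol: Chem.Mol) -> Chem.Mol:
    """Keep the largest organic fragment by heavy-atom count.

    Ties are broken by canonical SMILES so the choice is deterministic.
    A fragment is "organic" if it contains at least one carbon; if none does
    (e.g. pure inorganic input), the largest fragment is kept regardless.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    pool = organic or list(frags)
    return max(pool, key=lambda f: (heavy_atom_count(f), Chem.MolToSmiles(f)))


def canonical_smiles(mol: Chem.Mol) -> str:
    """Canonical isomeric SMILES (stereochemistry retained)."""
    return Chem.MolToSmiles(mol)


def heavy_atom_count(mol: Chem.Mol) -> int:
    """Number of non-hydrogen, non-dummy atoms."""
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def clear_dummy_labels(mol: Chem.Mol) -> Chem.Mol:
    """Return a copy with isotope and map labels wiped from dummy atoms."""
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetIsotope(0)
            atom.SetAtomMapNum(0)
    return out


def dummy_output_positions(mol: Chem.Mol) -> tuple[str, list[int]]:
    """Canonical SMILES of ``mol`` plus its dummy-atom indices in canonical
    SMILES output order.

    The output order defines the site numbering used throughout the package:
    site *i* of a core is the *i*-th dummy atom written in the canonical
    SMILES. Because canonical ranking is a graph invariant, two isomorphic
    cores number their sites compatibly.
    """
    smiles = Chem.MolToSmiles(mol)
    order = list(mol.GetPropsAsDict(True, True)["_smilesAtomOutputOrder"])
    dummies = [idx for idx in order if mol.GetAtomWithIdx(idx).GetAtomicNum() == 0]
    return smiles, dummies


def site_symmetry_classes(mol: Chem.Mol, dummy_indices: list[int]) -> tuple[int, ...]:
    """Symmetry class (automorphism orbit label) of each listed dummy atom.

    Sites sharing a class are topologically equivalent attachment points;
    substituent tuples are compared up to permutation within a class.
    """
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    return tuple(ranks[i] for i in dummy_indices)


def remove_dummies_with_h(mol: Chem.Mol) -> Chem.Mol | None:
    """Replace every dummy atom by an implicit hydrogen (core generalization).

    Returns None if the hydrogen-capped structure fails sanitization.
    """
    rw = Chem.RWMol(mol)
    for idx in sorted(
        (a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0), reverse=True
    ):
        neighbors = rw.GetAtomWithIdx(idx).GetNeighbors()
        rw.RemoveAtom(idx)
        for nb in neighbors:
            nb.SetNoImplicit(False)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except (Chem.AtomValenceException, Chem.KekulizeException, ValueError):
        return None
    return out


def _canon_fragment(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable fragment SMILES: {smiles!r}")
    return Chem.MolToSmiles(clear_dummy_labels(mol))


#: Canonical form of a bare-hydrogen substituent (an unsubstituted site).
H_SUBSTITUENT = _canon_fragment("[*][H]")


def weld(core_smiles: str, substituents: list[str]) -> Chem.Mol | None:
    """Attach substituents to a dummy-annotated core, one per site.

    ``core_smiles`` must contain exactly ``len(substituents)`` dummy atoms;
    substituent *i* (a single-dummy fragment SMILES, or :data:`H_SUBSTITUENT`
    for an unsubstituted site) is bonded at site *i* in canonical site order.
    Returns the sanitized molecule, or None if assembly fails chemically.
    """
    core = Chem.MolFromSmiles(core_smiles)
    if core is None:
        return None
    core = clear_dummy_labels(core)
    _, dummy_idx = dummy_output_positions(core)
    if len(dummy_idx) != len(substituents):
        raise ValueError(
            f"core has {len(dummy_idx)} sites, got {len(substituents)} substituents"
        )
    h_sites = []
    combined = Chem.RWMol(core)
    for site, (didx, sub) in enumerate(zip(dummy_idx, substituents), start=1):
        combined.GetAtomWithIdx(didx).SetAtomMapNum(site)
        if sub == H_SUBSTITUENT:
            h_sites.append(site)
            continue
        frag = Chem.MolFromSmiles(sub)
        if frag is None:
            return None
        frag = clear_dummy_labels(frag)
        fdummies = [a for a in frag.GetAtoms() if a.GetAtomicNum() == 0]
        if len(fdummies) != 1:
            raise ValueError(f"substituent must have exactly one dummy: {sub!r}")
        fdummies[0].SetAtomMapNum(site)
        combined = Chem.RWMol(Chem.CombineMols(combined.GetMol(), frag))
    mol = combined.GetMol()
    if h_sites:
        rw = Chem.RWMol(mol)
        for idx in sorted(
            (
                a.GetIdx()
                for a in rw.GetAtoms()
                if a.GetAtomicNum() == 0 and a.GetAtomMapNum() in h_sites
            ),
            reverse=True,
        ):
            neighbors = rw.GetAtomWithIdx(idx).GetNeighbors()
            rw.RemoveAtom(idx)
            for nb in neighbors:
                nb.SetNoImplicit(False)
        mol = rw.GetMol()
    try:
        if any(a.GetAtomicNum() == 0 and a.GetAtomMapNum() for a in mol.GetAtoms()):
            mol = Chem.molzip(mol)
        Chem.SanitizeMol(mol)
    except (Chem.AtomValenceException, Chem.KekulizeException, RuntimeError, ValueError):
        return None
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return mol
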