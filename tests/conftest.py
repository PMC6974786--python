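"""Shared test fixtures: generated compound collections and an independent
brute-force fragmentation oracle.

The oracle deliberately takes a different mechanical route from the library
(bond deletion on an editable molecule + fragment SMILES writing, instead of
FragmentOnBonds with dummy bookkeeping) so that agreement between the two is
meaningful.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import pytest
from hypothesis import settings as hypothesis_settings
from rdkit import Chem

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from cliff3 import activity_data as ad
from cliff3.fixtures import (
    additive_fixture_spec,
    dominant_fixture_spec,
    generate,
    standard_fixture_spec,
    synergy_fixture_spec,
    write_fixture,
)
from cliff3.pipeline import RunConfig, run_pipeline
from cliff3.recap import find_cleavable_bonds

# A small panel of real drug-like molecules exercising diverse bond types
# (amides, esters, ethers, amines, sulfonamides, biaryls, ureas, lactams).
DRUG_SMILES = [
    "CC(=O)Nc1ccc(O)cc1",                         # paracetamol
    "CC(=O)Oc1ccccc1C(=O)O",                      # aspirin
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",                 # ibuprofen
    "Cn1c(=O)c2c(ncn2C)n(C)c1=O",                 # caffeine
    "CCN(CC)CCOC(c1ccccc1)c1ccccc1",              # diphenhydramine-like
    "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1",            # sulfamethoxazole-like
    "CCN(CC)CC(=O)Nc1c(C)cccc1C",                 # lidocaine
    "CCCCNC(=O)Nc1ccc(Cl)cc1",                    # an aryl urea
    "O=C1CCCN1Cc1ccccc1",                         # N-benzyl lactam
    "COc1ccc(-c2ccccc2)cc1",                      # methoxybiphenyl
    "CCOC(=O)c1ccc(N)cc1",                        # benzocaine
    "CN1CCC(OC(=O)c2ccccc2)CC1",                  # an amino ester
    "Cc1ccc(S(=O)(=O)N(C)C)cc1",                  # sulfonamide
    "O=C(Nc1ccccc1)c1ccccc1",                     # benzanilide
    "C[N+](C)(C)Cc1ccccc1",                       # quaternary ammonium
]


@pytest.fixture(scope="session")
def standard_fixture():
    """(activity table DataFrame, ground-truth dict) at seed 1."""
    return generate(standard_fixture_spec(1))


@pytest.fixture(scope="session")
def fixture_molecule_smiles(standard_fixture):
    """≥ 50 parseable structures: all fixture series members plus drugs."""
    table, truth = standard_fixture
    smiles = [
        info["smiles"]
        for t in truth["targets"].values()
        for cid, info in t["compounds"].items()
        if not cid.split("-")[1].startswith("F")  # skip pair-less fillers
    ]
    return smiles + DRUG_SMILES


def target_sets_from_table(table):
    records = [
        ad.ActivityRecord(r.compound_id, r.smiles, r.target_id, r.pki, i)
        for i, r in enumerate(table.itertuples(index=False), start=2)
    ]
    return ad.build_target_sets(records)


@pytest.fixture(scope="session")
def standard_target_sets(standard_fixture):
    return target_sets_from_table(standard_fixture[0])


def run_fixture_pipeline(spec_fn, tmp_root: Path, seed: int = 1, **config_overrides):
    """Generate a stock fixture, run the full pipeline, return (outdir, truth)."""
    import json

    tsv, sidecar = write_fixture(spec_fn(seed), tmp_root / "fx")
    config = RunConfig(
        input_path=str(tsv), out_dir=str(tmp_root / "run"), seed=seed,
        **config_overrides,
    )
    out = run_pipeline(config)
    return out, json.loads(Path(sidecar).read_text())


@pytest.fixture(scope="session")
def standard_run(tmp_path_factory):
    return run_fixture_pipeline(
        standard_fixture_spec, tmp_path_factory.mktemp("std")
    )


@pytest.fixture(scope="session")
def additive_run(tmp_path_factory):
    return run_fixture_pipeline(
        additive_fixture_spec, tmp_path_factory.mktemp("add")
    )


@pytest.fixture(scope="session")
def dominant_run(tmp_path_factory):
    return run_fixture_pipeline(
        dominant_fixture_spec, tmp_path_factory.mktemp("dom")
    )


@pytest.fixture(scope="session")
def synergy_run(tmp_path_factory):
    return run_fixture_pipeline(
        synergy_fixture_spec, tmp_path_factory.mktemp("syn")
    )


# --- independent fragmentation oracle ---------------------------------------

def brute_force_core_splits(smiles: str, max_sites: int = 5) -> set[tuple]:
    """All valid core/substituent splits by exhaustive subset enumeration.

    Returns a set of comparison keys
    ``(generalized_core_smiles, site_count, sorted substituent SMILES)``
    where substituents are written hydrogen-capped. Bond subsets are cut by
    deleting bonds from an editable copy (implicit hydrogens restore the
    valence), the star-topology and 2× size rules are applied by direct
    counting, and fragments are written with ``MolFragmentToSmiles``.
    """
    mol = Chem.MolFromSmiles(smiles)
    bonds = find_cleavable_bonds(mol)
    keys: set[tuple] = set()
    for k in range(1, max_sites + 1):
        for subset in combinations(bonds, k):
            rw = Chem.RWMol(mol)
            for cb in subset:
                rw.RemoveBond(cb.atom_index_a, cb.atom_index_b)
            for cb in subset:
                for idx in (cb.atom_index_a, cb.atom_index_b):
                    rw.GetAtomWithIdx(idx).SetNoImplicit(False)
            cut = rw.GetMol()
            try:
                Chem.SanitizeMol(cut)
            except (Chem.AtomValenceException, Chem.KekulizeException, ValueError):
                continue
            frags = Chem.GetMolFrags(cut)
            if len(frags) != k + 1:
                continue
            endpoint_sets = [
                {cb.atom_index_a, cb.atom_index_b} for cb in subset
            ]
            for core_atoms in frags:
                core_set = set(core_atoms)
                # the core must touch every cut bond
                if not all(core_set & ep for ep in endpoint_sets):
                    continue
                heavy = lambda atoms: sum(
                    1 for i in atoms if cut.GetAtomWithIdx(i).GetAtomicNum() > 1
                )
                core_heavy = heavy(core_atoms)
                sub_heavy = sum(
                    heavy(f) for f in frags if set(f) != core_set
                )
                if core_heavy < 2 * sub_heavy:
                    continue
                core_smi = Chem.CanonSmiles(
                    Chem.MolFragmentToSmiles(cut, atomsToUse=list(core_atoms))
                )
                subs = sorted(
                    Chem.CanonSmiles(
                        Chem.MolFragmentToSmiles(cut, atomsToUse=list(f))
                    )
                    for f in frags
                    if set(f) != core_set
                )
                keys.add((core_smi, k, tuple(subs)))
    return keys
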