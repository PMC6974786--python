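"""Deterministic synthetic compound collections with known ground truth.

Each fixture target is an R-group enumeration around one scaffold: compounds
are assembled by welding substituents onto a dummy-marked scaffold SMILES,
and potencies follow an additive R-group model

    pKi = baseline + Σ_site increment(substituent) + interaction + ε,

with ε Gaussian and optional pairwise interaction terms (planted synergy).
Cliffs are planted by giving selected substituents a large increment. The
generator emits the interchange activity table plus a ground-truth sidecar:
true series membership, true pair site counts, the analytic Δ distribution
moments, and the planted cliff pairs. For planted targets it verifies the
separation margins (planted Δ above mean + 3σ, all other Δ below mean + 1σ)
and refuses to generate a fixture that violates them.

What this emulates — and what it does not: series structure, replicated
scaffolds, additive SAR with noise. It makes no attempt at drug-likeness,
chemical diversity, or assay artifacts.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from .chem import (
    H_SUBSTITUENT,
    canonical_smiles,
    clear_dummy_labels,
    dummy_output_positions,
    heavy_atom_count,
    parse_smiles,
    weld,
)

__all__ = ["TargetFixtureSpec", "FixtureSpec", "generate", "write_fixture",
           "standard_fixture_spec", "additive_fixture_spec",
           "dominant_fixture_spec", "synergy_fixture_spec"]


@dataclass(frozen=True)
class TargetFixtureSpec:
    """One synthetic target set built around a single scaffold.

    ``scaffold`` is a SMILES with one dummy atom per substitution site;
    ``alphabets`` / ``increments`` align with the dummy atoms in the order
    they appear in the SMILES string. Substituents are single-dummy fragment
    SMILES; :data:`~cliff3.chem.H_SUBSTITUENT` leaves a site unsubstituted.
    ``extra_members`` adds substituent combinations beyond the full
    factorial (this is how a single planted compound is introduced).
    """

    target_id: str
    scaffold: str
    alphabets: tuple[tuple[str, ...], ...]
    baseline_pki: float
    increments: tuple[dict[str, float], ...]
    noise_sd: float = 0.0
    extra_members: tuple[tuple[str, ...], ...] = ()
    #: (site index in written order, substituent) combinations that mark a
    #: compound as cliff-planted
    planted_substituents: frozenset = frozenset()
    #: ((sub at site 0, sub at site 1, ...), extra pKi) interaction terms
    interactions: tuple[tuple[tuple[str, ...], float], ...] = ()
    #: additional (smiles, pKi) compounds outside the scaffold series — they
    #: widen the set's potency distribution (the IQR gate sees the whole
    #: target set) without contributing analog pairs, and must therefore have
    #: no retrosynthetically cleavable bonds
    filler_compounds: tuple[tuple[str, float], ...] = ()
    enforce_margins: bool = True


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    targets: tuple[TargetFixtureSpec, ...]


class FixtureGenerationError(RuntimeError):
    pass


def _canon_sub(sub: str) -> str:
    mol = parse_smiles(sub)
    if mol is None:
        raise FixtureGenerationError(f"unparsable substituent SMILES {sub!r}")
    return canonical_smiles(clear_dummy_labels(mol))


def _scaffold_layout(scaffold: str) -> tuple[str, list[int]]:
    """Canonical dummy-core SMILES of the scaffold plus the permutation from
    written site order to canonical site order."""
    mol = parse_smiles(scaffold)
    if mol is None:
        raise FixtureGenerationError(f"unparsable scaffold SMILES {scaffold!r}")
    mol = clear_dummy_labels(mol)
    written = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    site_core, canonical = dummy_output_positions(mol)
    perm = [written.index(idx) for idx in canonical]  # canonical pos -> written pos
    return site_core, perm


def _generate_target(tspec: TargetFixtureSpec, rng: np.random.Generator) -> dict:
    site_core, perm = _scaffold_layout(tspec.scaffold)
    n_sites = len(perm)
    if len(tspec.alphabets) != n_sites or len(tspec.increments) != n_sites:
        raise FixtureGenerationError(
            f"{tspec.target_id}: scaffold has {n_sites} sites, "
            f"got {len(tspec.alphabets)} alphabets / {len(tspec.increments)} increments"
        )
    combos = list(itertools.product(*tspec.alphabets))
    combos.extend(tspec.extra_members)

    generalized_mol = weld(site_core, [H_SUBSTITUENT] * n_sites)
    generalized = canonical_smiles(generalized_mol) if generalized_mol else None

    compounds: dict[str, dict] = {}
    members: dict[str, tuple[str, ...]] = {}
    planted_ids: set[str] = set()
    seen_structures: dict[str, str] = {}
    for idx, combo in enumerate(combos, start=1):
        canon_combo = tuple(_canon_sub(s) for s in combo)
        mol = weld(site_core, [canon_combo[p] for p in perm])
        if mol is None:
            raise FixtureGenerationError(
                f"{tspec.target_id}: substituents {combo} do not assemble on "
                f"scaffold {tspec.scaffold}"
            )
        smiles = canonical_smiles(mol)
        if smiles in seen_structures:
            raise FixtureGenerationError(
                f"{tspec.target_id}: combos map to the same structure {smiles}"
            )
        pki = tspec.baseline_pki + sum(
            tspec.increments[site].get(sub, 0.0) for site, sub in enumerate(combo)
        )
        for subs, extra in tspec.interactions:
            if tuple(_canon_sub(s) for s in subs) == canon_combo:
                pki += extra
        pki += float(rng.normal(0.0, tspec.noise_sd)) if tspec.noise_sd > 0 else 0.0
        cid = f"{tspec.target_id}-{idx:03d}"
        seen_structures[smiles] = cid
        compounds[cid] = {"smiles": smiles, "pki": round(pki, 6),
                          "heavy_atoms": heavy_atom_count(mol)}
        members[cid] = tuple(canon_combo[p] for p in perm)  # canonical site order
        if any(
            (site, sub) in tspec.planted_substituents
            for site, sub in enumerate(combo)
        ):
            planted_ids.add(cid)

    from .recap import find_cleavable_bonds  # late import: fixtures sit above recap

    for f_idx, (smiles, pki) in enumerate(tspec.filler_compounds, start=1):
        mol = parse_smiles(smiles)
        if mol is None:
            raise FixtureGenerationError(f"{tspec.target_id}: bad filler SMILES {smiles!r}")
        canon = canonical_smiles(mol)
        if canon in seen_structures:
            raise FixtureGenerationError(f"{tspec.target_id}: duplicate filler {canon}")
        if find_cleavable_bonds(mol):
            raise FixtureGenerationError(
                f"{tspec.target_id}: filler {canon} has cleavable bonds and "
                "would contaminate the analog-pair distribution"
            )
        cid = f"{tspec.target_id}-F{f_idx:03d}"
        seen_structures[canon] = cid
        compounds[cid] = {"smiles": canon, "pki": round(float(pki), 6),
                          "heavy_atoms": heavy_atom_count(mol)}

    ids = sorted(members)  # analog pairs arise only among series members
    pairs = []
    for a, b in itertools.combinations(ids, 2):
        diff = sum(x != y for x, y in zip(members[a], members[b]))
        delta = abs(compounds[a]["pki"] - compounds[b]["pki"])
        planted = (a in planted_ids) != (b in planted_ids)
        pairs.append(
            {"lo": a if compounds[a]["pki"] <= compounds[b]["pki"] else b,
             "hi": b if compounds[a]["pki"] <= compounds[b]["pki"] else a,
             "differing_sites": diff, "delta_pki": round(delta, 6),
             "planted": planted}
        )
    deltas = np.array([p["delta_pki"] for p in pairs])
    mean = float(np.mean(deltas))
    sigma = float(np.std(deltas, ddof=1))
    pkis = np.array([info["pki"] for info in compounds.values()])
    q1, q3 = np.quantile(pkis, [0.25, 0.75])

    if tspec.planted_substituents and tspec.enforce_margins:
        planted_min = min(p["delta_pki"] for p in pairs if p["planted"])
        distractor_max = max(p["delta_pki"] for p in pairs if not p["planted"])
        if planted_min <= mean + 3 * sigma:
            raise FixtureGenerationError(
                f"{tspec.target_id}: planted Δ {planted_min:.3f} does not clear "
                f"mean+3σ = {mean + 3 * sigma:.3f}"
            )
        if distractor_max >= mean + sigma:
            raise FixtureGenerationError(
                f"{tspec.target_id}: distractor Δ {distractor_max:.3f} reaches "
                f"mean+1σ = {mean + sigma:.3f}"
            )

    return {
        "series": {
            "site_core_smiles": site_core,
            "core_smiles": generalized,
            "site_count": n_sites,
            "members": {cid: list(members[cid]) for cid in ids},
        },
        "compounds": {cid: compounds[cid] for cid in sorted(compounds)},
        "pairs": pairs,
        "n_pairs": len(pairs),
        "delta_mean": round(mean, 9),
        "delta_sigma": round(sigma, 9),
        "threshold": round(mean + 2 * sigma, 9),
        "iqr": round(float(q3 - q1), 9),
        "planted_pairs": sorted(
            [p["lo"], p["hi"]] for p in pairs if p["planted"]
        ),
    }


def generate(spec: FixtureSpec) -> tuple[pd.DataFrame, dict]:
    """Build the activity table and the ground-truth sidecar for a fixture.

    The same seed always yields byte-identical output (one child RNG per
    target, derived from the seed and the target's position).
    """
    truth: dict = {"seed": spec.seed, "targets": {}}
    rows = []
    for t_index, tspec in enumerate(spec.targets):
        rng = np.random.default_rng([spec.seed, t_index])
        ttruth = _generate_target(tspec, rng)
        truth["targets"][tspec.target_id] = ttruth
        for cid, info in ttruth["compounds"].items():
            rows.append((tspec.target_id, cid, info["smiles"], info["pki"]))
    table = pd.DataFrame(rows, columns=["target_id", "compound_id", "smiles", "pki"])
    return table, truth


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> tuple[Path, Path]:
    """Write the interchange TSV and ground-truth JSON; returns both paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth = generate(spec)
    tsv = outdir / "activities.tsv"
    sidecar = outdir / "ground_truth.json"
    table.to_csv(tsv, sep="\t", index=False, float_format="%.6f")
    sidecar.write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return tsv, sidecar


# --- stock fixture specifications ------------------------------------------

# Two-site scaffold: an aryl ether site (O–R1) and a tertiary-amine site
# (N–R2), both retrosynthetically cleavable; the scaffold is large enough to
# dominate any substituent combination under the 2× size rule.
_SCAFFOLD_2SITE = "[*]Oc1ccc(CN(Cc2ccc(Cl)cc2)[*])cc1C"
_ALKYL_R1 = ("[*]C", "[*]CC", "[*]CCC", "[*]C(C)C", "[*]CCCC", "[*]CC(C)C")
_ALKYL_R2 = ("[*]C", "[*]CC", "[*]CCC", "[*]C(C)C", "[*]CCCC", "[*]CCC(C)C")
_PLANTED_R1 = "[*]C(C)(C)C"

# One-site scaffold: benzamide with a variable aryl-ether substituent.
_SCAFFOLD_1SITE = "[*]Oc1ccc(C(=O)NCc2ccccc2)cc1"
_R1_SMALL = ("[*][H]", "[*]C", "[*]CC", "[*]CCC", "[*]C(C)C", "[*]CCCC",
             "[*]CC(C)C", "[*]CCCCC")

# Pair-less fillers: fused (hetero)aromatics decorated with ring-bound
# halogen/methyl/hydroxy groups — none of their bonds is retrosynthetically
# cleavable, so they broaden the target set's potency distribution without
# entering any analog series.
_FILLER_BASES = (
    "c1ccc2ccccc2c1",            # naphthalene
    "c1ccc2ncccc2c1",            # quinoline
    "c1ccc2cnccc2c1",            # isoquinoline
    "c1ccc2[nH]ccc2c1",          # indole
    "c1ccc2occc2c1",             # benzofuran
    "c1ccc2sccc2c1",             # benzothiophene
    "c1ccc2cc3ccccc3cc2c1",      # anthracene
    "c1ccc2c(c1)ccc1ccccc12",    # phenanthrene
)
_FILLER_GROUPS = ("F", "Cl", "Br", "C", "O")


def _filler_set(lo_pki: float, hi_pki: float) -> tuple[tuple[str, float], ...]:
    smiles = [g + base for base in _FILLER_BASES for g in _FILLER_GROUPS]
    step = (hi_pki - lo_pki) / (len(smiles) - 1)
    return tuple((s, round(lo_pki + i * step, 3)) for i, s in enumerate(smiles))


def standard_fixture_spec(seed: int = 1) -> FixtureSpec:
    """The package's standard two-target fixture.

    Target FT1 carries one planted high-potency compound (a tert-butyl ether
    with a +4.0 increment) among a 6×6 factorial of small alkyl analogs with
    increments ≤ 0.3 and noise σ = 0.05: its pairs are unambiguous cliffs
    while every distractor pair stays far below the detection threshold.
    Target FT2 spans well under one pKi log unit and exercises the IQR gate.
    """
    inc_r1 = dict(zip(_ALKYL_R1, (0.0, 0.05, 0.1, 0.15, 0.2, 0.3)))
    inc_r2 = dict(zip(_ALKYL_R2, (0.0, 0.05, 0.1, 0.15, 0.25, 0.3)))
    inc_r1[_PLANTED_R1] = 4.0
    ft1 = TargetFixtureSpec(
        target_id="FT1",
        scaffold=_SCAFFOLD_2SITE,
        alphabets=(_ALKYL_R1, _ALKYL_R2),
        baseline_pki=6.0,
        increments=(inc_r1, inc_r2),
        noise_sd=0.05,
        extra_members=((_PLANTED_R1, "[*]CCC"),),
        planted_substituents=frozenset({(0, _PLANTED_R1)}),
        filler_compounds=_filler_set(5.0, 11.0),
    )
    inc_small = dict(zip(_R1_SMALL, (0.0, 0.03, 0.06, 0.09, 0.12, 0.15, 0.18, 0.21)))
    ft2 = TargetFixtureSpec(
        target_id="FT2",
        scaffold=_SCAFFOLD_1SITE,
        alphabets=(_R1_SMALL,),
        baseline_pki=7.0,
        increments=(inc_small,),
        noise_sd=0.05,
    )
    return FixtureSpec(seed=seed, targets=(ft1, ft2))


def additive_fixture_spec(seed: int = 1) -> FixtureSpec:
    """Noise-free additive fixture for dual-site decomposition.

    Both sites carry one large-increment substituent (+2.0 and +2.2) inside
    5+1 × 5+1 factorials; potencies are exactly additive, so every dual-site
    cliff decomposes into two measured single-site gains that sum to Δdual.
    """
    r1 = _ALKYL_R1[:5] + ("[*]C(C)(C)C",)
    r2 = _ALKYL_R2[:5] + ("[*]CC(C)(C)C",)
    inc1 = dict(zip(r1, (0.0, 0.1, 0.15, 0.2, 0.3, 2.0)))
    inc2 = dict(zip(r2, (0.0, 0.05, 0.1, 0.2, 0.25, 2.2)))
    return FixtureSpec(
        seed=seed,
        targets=(
            TargetFixtureSpec(
                target_id="FTADD",
                scaffold=_SCAFFOLD_2SITE,
                alphabets=(r1, r2),
                baseline_pki=6.0,
                increments=(inc1, inc2),
                noise_sd=0.0,
            ),
        ),
    )


def dominant_fixture_spec(seed: int = 1) -> FixtureSpec:
    """Noise-free fixture where one substitution carries 95% of the dual Δ.

    The factorial is plain 5×5; the strong substituent S1 (+3.8) and the
    weak one S2 (+0.2) enter only through three extra compounds — (S1, b₀),
    (a₀, S2) and (S1, S2) — so that the dual-site cliff (a₀, b₀) → (S1, S2)
    has both single-site hybrids measured while strong-substituent pairs stay
    rare enough not to mask the threshold.
    """
    s1, s2 = "[*]C(C)(C)C", "[*]CC(C)(C)C"
    inc1 = dict(zip(_ALKYL_R1[:5], (0.0, 0.1, 0.15, 0.2, 0.3)))
    inc2 = dict(zip(_ALKYL_R2[:5], (0.0, 0.05, 0.1, 0.2, 0.25)))
    inc1[s1] = 3.8
    inc2[s2] = 0.2
    return FixtureSpec(
        seed=seed,
        targets=(
            TargetFixtureSpec(
                target_id="FTDOM",
                scaffold=_SCAFFOLD_2SITE,
                alphabets=(_ALKYL_R1[:5], _ALKYL_R2[:5]),
                baseline_pki=6.0,
                increments=(inc1, inc2),
                noise_sd=0.0,
                extra_members=(
                    (s1, _ALKYL_R2[0]),
                    (_ALKYL_R1[0], s2),
                    (s1, s2),
                ),
                filler_compounds=_filler_set(4.5, 9.3),
            ),
        ),
    )


def synergy_fixture_spec(seed: int = 1) -> FixtureSpec:
    """Additive fixture plus an explicit positive interaction term between
    the two large substituents (planted synergy)."""
    base = additive_fixture_spec(seed)
    t = base.targets[0]
    boosted = TargetFixtureSpec(
        target_id="FTSYN",
        scaffold=t.scaffold,
        alphabets=t.alphabets,
        baseline_pki=t.baseline_pki,
        increments=t.increments,
        noise_sd=0.0,
        interactions=((("[*]C(C)(C)C", "[*]CC(C)(C)C"), 1.5),),
    )
    return FixtureSpec(seed=seed, targets=(boosted,))
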