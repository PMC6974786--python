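"""Reading, validation and aggregation of compound activity records.

Input is a delimited table (ChEMBL-export-like) or an SD file with potency
values. Potency must be pKi — the negative decadic logarithm of the
equilibrium inhibition constant in molar units — or a Ki convertible to it.
Records are salt-stripped (largest organic fragment), canonicalized with
stereochemistry retained, and aggregated per (target, structure).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import pandas as pd
from rdkit import Chem

from .chem import canonical_smiles, heavy_atom_count, parse_smiles, strip_salts

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityRecord",
    "Compound",
    "TargetSet",
    "Rejection",
    "ColumnMap",
    "ki_nm_to_pki",
    "read_activity_table",
    "read_activity_sdf",
    "build_target_sets",
    "mean_policy",
    "median_policy",
    "discard_if_range_exceeds",
    "write_target_sets_tsv",
    "read_target_sets_tsv",
]

PKI_RANGE = (0.0, 15.0)  # plausible biological window; outside → warning only


@dataclass(frozen=True)
class ActivityRecord:
    compound_id: str
    smiles: str
    target_id: str
    pki: float
    source_row: int


@dataclass(frozen=True)
class Compound:
    """One unique structure with its aggregated potency against one target."""

    compound_id: str
    canonical_smiles: str
    heavy_atom_count: int
    pki: float


@dataclass(frozen=True)
class TargetSet:
    """All curated compounds active against one target protein."""

    target_id: str
    compounds: tuple[Compound, ...]

    @property
    def n(self) -> int:
        return len(self.compounds)


@dataclass(frozen=True)
class Rejection:
    source_row: int
    compound_id: str
    reason: str


@dataclass(frozen=True)
class ColumnMap:
    """Names of the relevant columns in a delimited activity table."""

    compound_id: str = "compound_id"
    smiles: str = "smiles"
    target_id: str = "target_id"
    potency: str = "pki"
    #: optional unit column; rows with unit "nM"/"uM"/"M" hold Ki values that
    #: are converted, rows with unit "pKi" (or no unit column) are taken as is.
    unit: str | None = None


def ki_nm_to_pki(ki_nm: float) -> float:
    """pKi from a Ki given in nanomolar: ``9 − log10(Ki[nM])``."""
    return 9.0 - math.log10(ki_nm)


_UNIT_TO_PKI: dict[str, Callable[[float], float]] = {
    "pki": lambda v: v,
    "nm": ki_nm_to_pki,
    "um": lambda v: 6.0 - math.log10(v),
    "m": lambda v: -math.log10(v),
}


def read_activity_table(
    path: str | Path,
    column_map: ColumnMap = ColumnMap(),
    delimiter: str = "\t",
) -> tuple[list[ActivityRecord], list[Rejection]]:
    """Parse a delimited activity table into validated records.

    Rows that fail validation are not dropped silently: each one yields a
    :class:`Rejection` with its line number and reason. Missing configured
    columns raise ``KeyError``; an unreadable path raises ``OSError``.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    required = [column_map.compound_id, column_map.smiles, column_map.target_id,
                column_map.potency]
    if column_map.unit:
        required.append(column_map.unit)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"{path}: missing required column(s) {missing}")

    records: list[ActivityRecord] = []
    rejections: list[Rejection] = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        data = dict(zip(df.columns, row))
        cid = str(data[column_map.compound_id]).strip()
        smiles = str(data[column_map.smiles]).strip()
        target = str(data[column_map.target_id]).strip()
        raw = data[column_map.potency]
        try:
            value = float(raw)
        except (TypeError, ValueError):
            rejections.append(Rejection(pos, cid, f"non-numeric potency {raw!r}"))
            continue
        if column_map.unit:
            unit = str(data[column_map.unit]).strip().lower()
            conv = _UNIT_TO_PKI.get(unit)
            if conv is None:
                rejections.append(Rejection(pos, cid, f"unknown potency unit {unit!r}"))
                continue
            if unit != "pki" and value <= 0:
                rejections.append(Rejection(pos, cid, f"non-positive Ki {value!r}"))
                continue
            value = conv(value)
        if not math.isfinite(value):
            rejections.append(Rejection(pos, cid, f"non-finite pKi {value!r}"))
            continue
        if not (PKI_RANGE[0] < value < PKI_RANGE[1]):
            logger.warning(
                "row %d (%s): pKi %.3f outside typical range %s", pos, cid, value, PKI_RANGE
            )
        if parse_smiles(smiles) is None:
            rejections.append(Rejection(pos, cid, f"unparsable SMILES {smiles!r}"))
            continue
        records.append(ActivityRecord(cid, smiles, target, value, pos))
    for rej in rejections:
        logger.info("rejected row %d (%s): %s", rej.source_row, rej.compound_id, rej.reason)
    return records, rejections


def read_activity_sdf(
    path: str | Path,
    pki_property: str = "pKi",
    target_property: str = "target_id",
    id_property: str = "compound_id",
) -> tuple[list[ActivityRecord], list[Rejection]]:
    """Read activity records from an SD file with pKi as a named property."""
    records: list[ActivityRecord] = []
    rejections: list[Rejection] = []
    supplier = Chem.SDMolSupplier(str(path))
    for pos, mol in enumerate(supplier, start=1):
        if mol is None:
            rejections.append(Rejection(pos, "?", "unparsable SD record"))
            continue
        props = mol.GetPropsAsDict()
        cid = str(props.get(id_property, mol.GetProp("_Name") if mol.HasProp("_Name") else pos))
        if pki_property not in props or target_property not in props:
            rejections.append(
                Rejection(pos, cid, f"missing property {pki_property!r} or {target_property!r}")
            )
            continue
        try:
            pki = float(props[pki_property])
        except (TypeError, ValueError):
            rejections.append(Rejection(pos, cid, f"non-numeric {pki_property!r}"))
            continue
        if not math.isfinite(pki):
            rejections.append(Rejection(pos, cid, "non-finite pKi"))
            continue
        records.append(
            ActivityRecord(cid, Chem.MolToSmiles(mol), str(props[target_property]), pki, pos)
        )
    return records, rejections


# --- aggregation policies ---------------------------------------------------

def mean_policy(values: list[float]) -> float | None:
    return sum(values) / len(values)


def median_policy(values: list[float]) -> float | None:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else 0.5 * (s[mid - 1] + s[mid])


def discard_if_range_exceeds(r: float) -> Callable[[list[float]], float | None]:
    """Mean aggregation, but a measurement spread above ``r`` log units
    discards the compound (returns None)."""

    def policy(values: list[float]) -> float | None:
        if max(values) - min(values) > r:
            return None
        return sum(values) / len(values)

    policy.__name__ = f"discard_if_range_exceeds_{r}"
    return policy


def build_target_sets(
    records: Iterable[ActivityRecord],
    aggregation_policy: Callable[[list[float]], float | None] = mean_policy,
) -> list[TargetSet]:
    """Group records per target, canonicalize structures, aggregate replicates.

    Two records with the same salt-stripped canonical structure and target
    collapse into one :class:`Compound`; a policy returning None (e.g. the
    discard-on-wide-range policy) excludes the compound with a log entry.
    Sets come back sorted by target id, compounds by canonical SMILES.
    """
    grouped: dict[str, dict[str, list[ActivityRecord]]] = {}
    structures: dict[str, tuple[str, int]] = {}  # raw smiles -> (canonical, heavy)
    for rec in records:
        if rec.smiles not in structures:
            mol = parse_smiles(rec.smiles)
            if mol is None:
                logger.info("row %d: unparsable SMILES at aggregation, skipped", rec.source_row)
                continue
            mol = strip_salts(mol)
            structures[rec.smiles] = (canonical_smiles(mol), heavy_atom_count(mol))
        canon, _ = structures[rec.smiles]
        grouped.setdefault(rec.target_id, {}).setdefault(canon, []).append(rec)

    heavy_by_canon = {canon: heavy for canon, heavy in structures.values()}
    sets: list[TargetSet] = []
    for target_id in sorted(grouped):
        compounds = []
        for canon in sorted(grouped[target_id]):
            recs = grouped[target_id][canon]
            agg = aggregation_policy([r.pki for r in recs])
            if agg is None:
                logger.info(
                    "target %s: compound %s discarded by aggregation policy (pKi range %.2f)",
                    target_id, recs[0].compound_id,
                    max(r.pki for r in recs) - min(r.pki for r in recs),
                )
                continue
            cid = sorted(r.compound_id for r in recs)[0]
            compounds.append(Compound(cid, canon, heavy_by_canon[canon], agg))
        if compounds:
            sets.append(TargetSet(target_id, tuple(compounds)))
    return sets


# --- interchange format -----------------------------------------------------

_TSV_COLUMNS = ["target_id", "compound_id", "canonical_smiles", "heavy_atoms", "pki"]


def write_target_sets_tsv(sets: Iterable[TargetSet], path: str | Path) -> None:
    rows = [
        (ts.target_id, c.compound_id, c.canonical_smiles, c.heavy_atom_count, c.pki)
        for ts in sets
        for c in ts.compounds
    ]
    df = pd.DataFrame(rows, columns=_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_target_sets_tsv(path: str | Path) -> list[TargetSet]:
    df = pd.read_csv(path, sep="\t", dtype={"target_id": str, "compound_id": str})
    sets = []
    for target_id, grp in df.groupby("target_id", sort=True):
        compounds = tuple(
            Compound(str(r.compound_id), r.canonical_smiles, int(r.heavy_atoms), float(r.pki))
            for r in grp.sort_values("canonical_smiles").itertuples(index=False)
        )
        sets.append(TargetSet(str(target_id), compounds))
    return sets
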