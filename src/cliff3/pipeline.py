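"""End-to-end orchestration: ingest → series → stats → cliffs → decomposition.

Every stage writes a flat TSV (plus a JSON summary and a YAML manifest), all
fully determined by the input and the configuration: no timestamps, stable
sort orders, fixed float formatting. A run can be reproduced byte for byte
from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import activity_data as ad
from .analog_series import AnalogPair, build_series, deduplicate_pairs, enumerate_pairs
from .chem import parse_smiles
from .cliff_detection import (
    ActivityCliff,
    MmpSizeLimits,
    detect_cliffs,
    detect_rmmp_cliffs,
)
from .decomposition import classify_contribution, find_single_site_analogs, structure_index
from .fragmentation import (
    DEFAULT_SUBSET_CAP,
    MAX_SITES,
    CombinatorialCapExceeded,
    enumerate_core_splits,
)
from .potency_stats import TargetSetStats, compute_iqr, compute_threshold, preselect_target_sets
from .recap import DEFAULT_RECAP_RULES, load_rules

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_manifest"]

_FLOAT_FMT = "%.9g"


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one pipeline run (serialized into the manifest)."""

    input_path: str
    out_dir: str
    compound_id_column: str = "compound_id"
    smiles_column: str = "smiles"
    target_id_column: str = "target_id"
    potency_column: str = "pki"
    unit_column: str | None = None
    delimiter: str = "\t"
    aggregation: str = "mean"              # mean | median | discard_if_range_exceeds
    aggregation_range: float = 1.0
    min_iqr: float = 1.0
    quartile_mode: str = "linear"
    sigma_mode: str = "sample"
    strict_threshold: bool = False
    dedup_pairs: bool = True
    mode: str = "third"                    # third | second_rmmp | second_mmp
    max_sites: int = MAX_SITES
    subset_cap: int = DEFAULT_SUBSET_CAP
    recap_rules_yaml: str | None = None
    mmp_max_substituent: int = 13
    mmp_core_ratio: float = 2.0
    mmp_max_exchange_diff: int = 8
    dominance_fraction: float = 0.8
    effect_tolerance: float = 0.5
    seed: int = 0

    def to_manifest(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)


def load_manifest(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig(**data)


def _aggregation_policy(config: RunConfig):
    if config.aggregation == "mean":
        return ad.mean_policy
    if config.aggregation == "median":
        return ad.median_policy
    if config.aggregation == "discard_if_range_exceeds":
        return ad.discard_if_range_exceeds(config.aggregation_range)
    raise ValueError(f"unknown aggregation policy {config.aggregation!r}")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the output directory.

    Writes ``compounds.tsv``, ``rejections.tsv``, ``target_stats.tsv``,
    ``series.tsv``, ``pairs.tsv``, ``cliffs.tsv``, ``decomposition.tsv``,
    ``summary.json``, ``manifest.yaml`` and ``run.log``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cliff3")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> Path:
    rules = (
        load_rules(config.recap_rules_yaml)
        if config.recap_rules_yaml
        else DEFAULT_RECAP_RULES
    )
    column_map = ad.ColumnMap(
        compound_id=config.compound_id_column,
        smiles=config.smiles_column,
        target_id=config.target_id_column,
        potency=config.potency_column,
        unit=config.unit_column,
    )
    records, rejections = ad.read_activity_table(
        config.input_path, column_map, delimiter=config.delimiter
    )
    target_sets = ad.build_target_sets(records, _aggregation_policy(config))
    ad.write_target_sets_tsv(target_sets, out / "compounds.tsv")
    _write_tsv(
        pd.DataFrame(
            [(r.source_row, r.compound_id, r.reason) for r in rejections],
            columns=["source_row", "compound_id", "reason"],
        ),
        out / "rejections.tsv",
    )

    # --- step 1.0: IQR pre-selection ---------------------------------------
    base_stats: list[TargetSetStats] = []
    excluded: dict[str, str] = {}
    for ts in target_sets:
        if ts.n < 2:
            excluded[ts.target_id] = "fewer than 2 compounds"
            logger.info("target %s excluded: n=%d < 2", ts.target_id, ts.n)
            continue
        q1, q3, iqr = compute_iqr(ts, config.quartile_mode)
        base_stats.append(TargetSetStats(ts.target_id, ts.n, q1, q3, iqr))
    retained_ids = {s.target_id for s in preselect_target_sets(base_stats, config.min_iqr)}
    for st in base_stats:
        if st.target_id not in retained_ids:
            excluded[st.target_id] = f"IQR {st.iqr:.6g} below {config.min_iqr:.6g}"
    sets_by_id = {ts.target_id: ts for ts in target_sets}

    limits = MmpSizeLimits(
        max_substituent_heavy_atoms=config.mmp_max_substituent,
        min_core_to_substituent_ratio=config.mmp_core_ratio,
        max_exchange_size_difference=config.mmp_max_exchange_diff,
    )

    series_rows, pair_rows, cliff_rows, decomp_rows, stats_rows = [], [], [], [], []
    summary: dict = {"mode": config.mode, "targets": {}, "excluded": excluded}

    for st in base_stats:
        tid = st.target_id
        if tid not in retained_ids:
            continue
        ts = sets_by_id[tid]
        tsum: dict = {"n_compounds": ts.n, "iqr": st.iqr}

        # --- steps 2.1/2.2: series and pairs -------------------------------
        splits = {}
        for compound in ts.compounds:
            mol = parse_smiles(compound.canonical_smiles)
            try:
                splits[compound.compound_id] = enumerate_core_splits(
                    mol, config.max_sites, rules, config.subset_cap
                )
            except CombinatorialCapExceeded as exc:
                logger.info("target %s: compound %s skipped (%s)", tid,
                            compound.compound_id, exc)
        series = build_series(ts, splits)
        for s in series:
            series_rows.append((tid, s.core_smiles, s.site_core_smiles,
                                s.site_count, s.n))
        all_pairs: list[AnalogPair] = [p for s in series for p in enumerate_pairs(s)]
        pairs = deduplicate_pairs(all_pairs) if config.dedup_pairs else all_pairs
        for p in pairs:
            pair_rows.append((tid, p.compound_lo, p.compound_hi, p.differing_sites,
                              round(p.delta_pki, 9), p.core_smiles))
        tsum["n_series"] = len(series)
        tsum["n_pairs"] = len(pairs)

        # --- steps 3.1/3.2: Δ distribution and threshold --------------------
        if len(pairs) < 2:
            excluded[tid] = "fewer than 2 analog pairs"
            logger.info("target %s excluded: %d analog pair(s)", tid, len(pairs))
            summary["targets"][tid] = tsum
            continue
        full = compute_threshold(pairs, st, config.sigma_mode)
        stats_rows.append((tid, full.n_compounds, full.q1, full.q3, full.iqr,
                           full.n_pairs, full.delta_mean, full.delta_sigma,
                           full.threshold, True))
        tsum["threshold"] = full.threshold

        # --- step 4.1: cliff detection --------------------------------------
        if config.mode == "third":
            cliffs = detect_cliffs(pairs, full, strict=config.strict_threshold)
        elif config.mode in ("second_rmmp", "second_mmp"):
            cliffs = detect_rmmp_cliffs(
                ts, full, limits,
                restrict_to_recap=(config.mode == "second_rmmp"),
                rules=rules, strict=config.strict_threshold,
            )
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
        for c in cliffs:
            p = c.pair
            cliff_rows.append((tid, p.compound_lo, p.compound_hi,
                               round(p.pki_lo, 9), round(p.pki_hi, 9),
                               round(p.delta_pki, 9), p.differing_sites,
                               c.category, round(c.threshold_used, 9),
                               p.core_smiles, c.generation_mode))
        tsum["n_cliffs"] = len(cliffs)
        tsum["n_single_site"] = sum(1 for c in cliffs if c.category == "single_site")
        tsum["n_multi_site"] = sum(1 for c in cliffs if c.category == "multi_site")
        dual = [c for c in cliffs if c.site_count_of_pair == 2]
        tsum["n_dual_site"] = len(dual)

        # --- step 4.2: dual-site decomposition ------------------------------
        index = structure_index(ts.compounds)
        tallies = {"both_matches": 0, "determined_by_one": 0, "both_contribute": 0,
                   "unclassified": 0, "additive": 0, "synergistic": 0,
                   "compensatory": 0}
        for c in dual:
            matches = find_single_site_analogs(c, index)
            cls = classify_contribution(
                c, matches, config.dominance_fraction, config.effect_tolerance
            )
            if cls.matches_found == 2:
                tallies["both_matches"] += 1
            tallies[cls.pattern] += 1
            if cls.effect:
                tallies[cls.effect] += 1
            p = c.pair
            if matches:
                for m in matches:
                    decomp_rows.append((tid, p.compound_lo, p.compound_hi,
                                        round(p.delta_pki, 9), m.site_index,
                                        m.analog_id, round(m.delta_single, 9),
                                        cls.pattern, cls.effect or ""))
            else:
                decomp_rows.append((tid, p.compound_lo, p.compound_hi,
                                    round(p.delta_pki, 9), "", "", "",
                                    cls.pattern, ""))
        tsum["decomposition"] = tallies
        summary["targets"][tid] = tsum

    _write_tsv(pd.DataFrame(series_rows, columns=[
        "target_id", "core_smiles", "site_core_smiles", "site_count", "n_members",
    ]), out / "series.tsv")
    _write_tsv(pd.DataFrame(pair_rows, columns=[
        "target_id", "cpd_lo", "cpd_hi", "differing_sites", "delta_pki", "core_smiles",
    ]), out / "pairs.tsv")
    _write_tsv(pd.DataFrame(stats_rows, columns=[
        "target_id", "n_compounds", "q1", "q3", "iqr", "n_pairs", "delta_mean",
        "delta_sigma", "threshold", "retained",
    ]), out / "target_stats.tsv")
    _write_tsv(pd.DataFrame(cliff_rows, columns=[
        "target_id", "cpd_lo", "cpd_hi", "pki_lo", "pki_hi", "delta_pki",
        "differing_sites", "category", "threshold", "core_smiles", "generation_mode",
    ]), out / "cliffs.tsv")
    _write_tsv(pd.DataFrame(decomp_rows, columns=[
        "target_id", "cpd_lo", "cpd_hi", "delta_dual", "site", "analog_id",
        "delta_single", "pattern", "effect",
    ]), out / "decomposition.tsv")

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    (out / "manifest.yaml").write_text(config.to_manifest())
    return out
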