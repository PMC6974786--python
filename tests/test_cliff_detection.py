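"""Cliff calling: thresholds, categories, and the matched-pair mode."""

import json

import pandas as pd
import pytest

from cliff3 import activity_data as ad
from cliff3.analog_series import AnalogPair
from cliff3.cliff_detection import MmpSizeLimits, detect_cliffs, detect_rmmp_cliffs
from cliff3.potency_stats import TargetSetStats


def stats_with_threshold(threshold, target="T1"):
    return TargetSetStats(target, 10, 6.0, 8.0, 2.0, n_pairs=10,
                          delta_mean=threshold / 2, delta_sigma=threshold / 4,
                          threshold=threshold)


def pair(lo, hi, delta, diff=1):
    return AnalogPair(
        target_id="T1", site_core_smiles="*c1ccccc1", core_smiles="c1ccccc1",
        core_heavy_atoms=6, compound_lo=lo, compound_hi=hi,
        pki_lo=6.0, pki_hi=6.0 + delta,
        substituents_lo=("*C",) * diff, substituents_hi=("*N",) * diff,
        site_count=diff, site_classes=tuple(range(diff)), differing_sites=diff,
    )


class TestDetectCliffs:
    def test_threshold_separates_cliffs_from_ordinary_pairs(self):
        st = stats_with_threshold(1.107)
        cliffs = detect_cliffs([pair("a", "b", 2.7), pair("c", "d", 1.0)], st)
        assert [(c.pair.compound_lo, c.pair.compound_hi) for c in cliffs] == [("a", "b")]
        assert cliffs[0].generation_mode == "third"

    def test_boundary_is_inclusive_by_default_strict_optional(self):
        st = stats_with_threshold(1.0)
        at = [pair("a", "b", 1.0)]
        assert len(detect_cliffs(at, st)) == 1
        assert detect_cliffs(at, st, strict=True) == []

    def test_category_follows_differing_sites(self):
        st = stats_with_threshold(1.0)
        cliffs = detect_cliffs([pair("a", "b", 2.0, diff=2),
                                pair("c", "d", 2.0, diff=1)], st)
        cats = {c.pair.compound_lo: c.category for c in cliffs}
        assert cats == {"a": "multi_site", "c": "single_site"}
        assert all(
            (c.category == "single_site") == (c.site_count_of_pair == 1)
            for c in cliffs
        )

    def test_lowering_threshold_never_removes_a_cliff(self):
        pairs = [pair(f"a{i}", f"b{i}", d) for i, d in
                 enumerate([0.2, 0.8, 1.3, 2.0, 3.5])]
        keys = lambda cs: {(c.pair.compound_lo, c.pair.compound_hi) for c in cs}
        high = keys(detect_cliffs(pairs, stats_with_threshold(2.0)))
        low = keys(detect_cliffs(pairs, stats_with_threshold(1.0)))
        assert high <= low

    def test_single_plus_multi_equals_total(self, standard_run):
        out, _ = standard_run
        summary = json.loads((out / "summary.json").read_text())
        for t in summary["targets"].values():
            assert t["n_single_site"] + t["n_multi_site"] == t["n_cliffs"]


def tiny_set(entries):
    from cliff3.chem import parse_smiles

    compounds = tuple(
        ad.Compound(cid, ad.canonical_smiles(parse_smiles(smi)),
                    ad.heavy_atom_count(parse_smiles(smi)), pki)
        for cid, smi, pki in entries
    )
    return ad.TargetSet("T1", compounds)


class TestMatchedPairMode:
    def test_retrosynthetic_cut_yields_rmmp_cliff(self):
        # anisole vs phenetole around the aryl-ether core, ΔpKi = 2
        ts = tiny_set([("m1", "COc1ccc(CN(C)Cc2ccccc2)cc1", 6.0),
                       ("m2", "CCOc1ccc(CN(C)Cc2ccccc2)cc1", 8.0)])
        st = stats_with_threshold(1.0)
        cliffs = detect_rmmp_cliffs(ts, st)
        assert len(cliffs) == 1
        assert cliffs[0].generation_mode == "second_rmmp"
        assert cliffs[0].category == "single_site"

    def test_aliphatic_cut_is_mmp_but_not_rmmp(self):
        # alkylbenzenes differ only through a non-retrosynthetic C–C cut
        ts = tiny_set([("m1", "c1ccccc1CCCC", 6.0), ("m2", "c1ccccc1CCCCC", 8.0)])
        st = stats_with_threshold(1.0)
        assert detect_rmmp_cliffs(ts, st) == []
        mmp = detect_rmmp_cliffs(ts, st, restrict_to_recap=False)
        assert len(mmp) == 1
        assert mmp[0].generation_mode == "second_mmp"

    def test_substituent_size_limits_are_enforced(self):
        ts = tiny_set([("m1", "COc1ccc(CN(C)Cc2ccccc2)cc1", 6.0),
                       ("m2", "CCOc1ccc(CN(C)Cc2ccccc2)cc1", 8.0)])
        st = stats_with_threshold(1.0)
        tight = MmpSizeLimits(max_substituent_heavy_atoms=0)
        assert detect_rmmp_cliffs(ts, st, size_limits=tight) == []

    def test_rmmp_cliffs_are_single_site_third_generation_cliffs(self, standard_run):
        """With the same threshold, every matched-pair cliff must reappear
        among the analog-series single-site cliffs (its core is one of the
        single-cut cores the series machinery also enumerates)."""
        out, _ = standard_run
        stats = pd.read_csv(out / "target_stats.tsv", sep="\t")
        cliffs = pd.read_csv(out / "cliffs.tsv", sep="\t")
        compounds = ad.read_target_sets_tsv(out / "compounds.tsv")
        third_single = {
            (r.target_id, *sorted((r.cpd_lo, r.cpd_hi)))
            for r in cliffs.itertuples()
            if r.differing_sites == 1
        }
        found_any = False
        for ts in compounds:
            row = stats[stats.target_id == ts.target_id]
            if row.empty:
                continue
            st_full = TargetSetStats(
                ts.target_id, ts.n, float(row.q1.iloc[0]), float(row.q3.iloc[0]),
                float(row.iqr.iloc[0]), int(row.n_pairs.iloc[0]),
                float(row.delta_mean.iloc[0]), float(row.delta_sigma.iloc[0]),
                float(row.threshold.iloc[0]),
            )
            for cliff in detect_rmmp_cliffs(ts, st_full):
                found_any = True
                key = (ts.target_id, *sorted((cliff.pair.compound_lo,
                                              cliff.pair.compound_hi)))
                assert key in third_single
        assert found_any, "fixture produced no matched-pair cliffs to compare"
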