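"""Series grouping, pair enumeration, differing-site counting, dedup."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from cliff3 import activity_data as ad
from cliff3.analog_series import (
    AnalogPair,
    build_series,
    count_differing_sites,
    deduplicate_pairs,
    enumerate_pairs,
)
from cliff3.chem import H_SUBSTITUENT, parse_smiles
from cliff3.fragmentation import enumerate_core_splits


def make_set(entries, target="T1"):
    compounds = tuple(
        ad.Compound(cid, ad.canonical_smiles(ad.strip_salts(parse_smiles(smi))),
                    ad.heavy_atom_count(parse_smiles(smi)), pki)
        for cid, smi, pki in entries
    )
    return ad.TargetSet(target, compounds)


def series_for(entries, **kw):
    ts = make_set(entries)
    splits = {
        c.compound_id: enumerate_core_splits(parse_smiles(c.canonical_smiles))
        for c in ts.compounds
    }
    return ts, build_series(ts, splits, **kw)


ANILIDES = [  # acyl variations on a shared naphthylamide core
    ("a1", "CC(=O)Nc1ccc2ccccc2c1", 6.0),
    ("a2", "CCC(=O)Nc1ccc2ccccc2c1", 6.5),
    ("a3", "CCCC(=O)Nc1ccc2ccccc2c1", 7.0),
    ("a4", "CC(C)C(=O)Nc1ccc2ccccc2c1", 8.0),
]


class TestBuildSeries:
    def test_four_compounds_sharing_a_core_form_one_series(self):
        _, series = series_for(ANILIDES)
        by_members = {s.site_core_smiles: s.n for s in series}
        assert 4 in by_members.values()  # the shared anilide-N core

    def test_singleton_cores_are_dropped(self):
        _, series = series_for([("a1", "CC(=O)Nc1ccc(O)cc1", 6.0),
                                ("b1", "CCOC(=O)c1ccccc1", 7.0)])
        assert series == []

    def test_compound_with_two_cores_joins_both_series(self):
        # ester + ether: each single cut defines its own core
        entries = [
            ("e1", "CCOC(=O)c1ccc(OC)cc1", 6.0),
            ("e2", "CCCOC(=O)c1ccc(OC)cc1", 6.5),   # shares the acid core
            ("e3", "CCOC(=O)c1ccc(OCC)cc1", 7.0),   # shares the ester-side core
        ]
        _, series = series_for(entries)
        membership = {
            s.site_core_smiles: {m.compound_id for m in s.members} for s in series
        }
        in_both = [cids for cids in membership.values() if "e1" in cids]
        assert len(in_both) >= 2

    def test_bare_core_compound_joins_as_all_hydrogen_member(self):
        entries = ANILIDES + [("a0", "Nc1ccc2ccccc2c1", 5.5)]
        _, series = series_for(entries)
        target = [s for s in series if s.n == 5]
        assert target, "bare core did not join its series"
        member = {m.compound_id: m.substituents for m in target[0].members}["a0"]
        assert all(sub == H_SUBSTITUENT for sub in member)


class TestEnumeratePairs:
    def test_pair_count_is_n_choose_2(self, standard_target_sets):
        from cliff3.fragmentation import enumerate_core_splits as ecs

        ts = standard_target_sets[0]
        splits = {
            c.compound_id: ecs(parse_smiles(c.canonical_smiles))
            for c in ts.compounds
        }
        for s in build_series(ts, splits):
            assert len(enumerate_pairs(s)) == s.n * (s.n - 1) // 2

    def test_differing_sites_and_delta(self):
        _, series = series_for(ANILIDES)
        s = max(series, key=lambda s: s.n)
        pairs = enumerate_pairs(s)
        by_ids = {(p.compound_lo, p.compound_hi): p for p in pairs}
        p = by_ids[("a1", "a2")]
        assert p.differing_sites == 1
        assert p.delta_pki == pytest.approx(0.5)
        assert all(p.pki_lo <= p.pki_hi for p in pairs)
        assert all(p.delta_pki >= 0 for p in pairs)

    def test_two_site_pair_arithmetic(self, additive_run):
        """In the noise-free factorial, pairs differing in both substituents
        carry the sum of both increments."""
        import pandas as pd

        out, truth = additive_run
        pairs = pd.read_csv(out / "pairs.tsv", sep="\t")
        truth_pairs = {
            tuple(sorted((p["lo"], p["hi"]))): p
            for p in truth["targets"]["FTADD"]["pairs"]
        }
        for row in pairs.itertuples():
            tp = truth_pairs[tuple(sorted((row.cpd_lo, row.cpd_hi)))]
            assert row.differing_sites <= tp["differing_sites"]
            assert math.isclose(row.delta_pki, tp["delta_pki"], abs_tol=1e-6)


class TestCountDifferingSites:
    def test_single_position_difference(self):
        assert count_differing_sites(("*C", "*Cl"), ("*CC", "*Cl"), (0, 1)) == 1

    def test_two_position_difference(self):
        assert count_differing_sites(("*C", "*Cl"), ("*CC", "*Br"), (0, 1)) == 2

    def test_equivalent_sites_compare_as_multisets(self):
        # both sites in one symmetry orbit: (Me, Cl) vs (Cl, Me) is no change
        assert count_differing_sites(("*C", "*Cl"), ("*Cl", "*C"), (0, 0)) == 0
        assert count_differing_sites(("*C", "*Cl"), ("*Cl", "*CC"), (0, 0)) == 1

    @given(st.lists(st.sampled_from(["*C", "*N", "*O", "*Cl"]),
                    min_size=1, max_size=5),
           st.data())
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_bounded(self, a, data):
        b = data.draw(st.lists(st.sampled_from(["*C", "*N", "*O", "*Cl"]),
                               min_size=len(a), max_size=len(a)))
        classes = data.draw(st.lists(st.integers(0, 2),
                                     min_size=len(a), max_size=len(a)))
        d_ab = count_differing_sites(a, b, classes)
        assert d_ab == count_differing_sites(b, a, classes)
        assert 0 <= d_ab <= len(a)
        assert count_differing_sites(a, a, classes) == 0


def _pair(lo, hi, diff, core_heavy, core="*c1ccccc1", delta=1.0):
    return AnalogPair(
        target_id="T1", site_core_smiles=core, core_smiles="c1ccccc1",
        core_heavy_atoms=core_heavy, compound_lo=lo, compound_hi=hi,
        pki_lo=6.0, pki_hi=6.0 + delta,
        substituents_lo=("*C",) * diff, substituents_hi=("*N",) * diff,
        site_count=diff, site_classes=tuple(range(diff)), differing_sites=diff,
    )


class TestDeduplicatePairs:
    def test_minimum_differing_sites_wins(self):
        out = deduplicate_pairs([
            _pair("c1", "c2", 2, core_heavy=10, core="*A*"),
            _pair("c1", "c2", 1, core_heavy=8, core="*B"),
        ])
        assert len(out) == 1 and out[0].differing_sites == 1

    def test_tie_broken_by_larger_core(self):
        out = deduplicate_pairs([
            _pair("c1", "c2", 1, core_heavy=8, core="*B"),
            _pair("c1", "c2", 1, core_heavy=12, core="*C"),
        ])
        assert out[0].core_heavy_atoms == 12

    def test_distinct_pairs_sharing_a_compound_both_kept(self):
        out = deduplicate_pairs([
            _pair("c1", "c2", 1, core_heavy=8),
            _pair("c1", "c3", 1, core_heavy=8),
        ])
        assert len(out) == 2
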