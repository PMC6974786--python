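"""Dual-site cliff decomposition: hybrid search and effect classification."""

import json

import pytest
from rdkit import Chem

from cliff3.analog_series import AnalogPair
from cliff3.chem import weld
from cliff3.cliff_detection import ActivityCliff
from cliff3.decomposition import (
    SingleSiteAnalogMatch,
    classify_contribution,
    find_single_site_analogs,
    structure_index,
)

CORE = "*Oc1ccc(CN(*)Cc2ccc(Cl)cc2)cc1C"


def dual_cliff(delta, subs_lo=("*C", "*C"), subs_hi=("*CC", "*CCC")):
    pair = AnalogPair(
        target_id="T1", site_core_smiles=CORE, core_smiles="",
        core_heavy_atoms=18, compound_lo="lo", compound_hi="hi",
        pki_lo=6.0, pki_hi=6.0 + delta,
        substituents_lo=subs_lo, substituents_hi=subs_hi,
        site_count=2, site_classes=(0, 1), differing_sites=2,
    )
    return ActivityCliff(pair, "T1", "multi_site", 2, 1.0, "third")


def match(site, delta):
    return SingleSiteAnalogMatch(site, f"analog{site}", 6.0 + delta, delta)


class TestClassifyContribution:
    @pytest.mark.parametrize("ddual,d1,d2,pattern,effect", [
        (2.5, 2.4, 0.1, "determined_by_one", None),
        (2.5, 1.2, 1.3, "both_contribute", "additive"),
        (3.0, 0.8, 0.9, "both_contribute", "synergistic"),
        (2.0, -0.6, 2.8, "both_contribute", "compensatory"),
    ])
    def test_rule_arithmetic(self, ddual, d1, d2, pattern, effect):
        cls = classify_contribution(
            dual_cliff(ddual), [match(1, d1), match(2, d2)]
        )
        assert (cls.pattern, cls.effect) == (pattern, effect)

    def test_overshooting_sum_is_compensatory(self):
        cls = classify_contribution(dual_cliff(2.0), [match(1, 1.5), match(2, 1.5)])
        assert cls.effect == "compensatory"

    def test_site_labels_are_interchangeable(self):
        for d1, d2 in [(2.4, 0.1), (1.2, 1.3), (0.8, 0.9)]:
            a = classify_contribution(dual_cliff(2.5), [match(1, d1), match(2, d2)])
            b = classify_contribution(dual_cliff(2.5), [match(1, d2), match(2, d1)])
            assert (a.pattern, a.effect) == (b.pattern, b.effect)

    def test_no_matches_is_unclassified(self):
        cls = classify_contribution(dual_cliff(2.5), [])
        assert cls.pattern == "unclassified" and cls.effect is None

    def test_single_dominant_match(self):
        assert classify_contribution(
            dual_cliff(2.5), [match(1, 2.4)]
        ).pattern == "determined_by_one"
        assert classify_contribution(
            dual_cliff(2.5), [match(1, 0.4)]
        ).pattern == "unclassified"


class TestHybridSearch:
    def test_both_hybrids_found_when_present(self):
        lo = weld(CORE, ["*C", "*C"])
        hi = weld(CORE, ["*CC", "*CCC"])
        hy1 = weld(CORE, ["*CC", "*C"])
        hy2 = weld(CORE, ["*C", "*CCC"])

        class C:  # minimal Compound stand-in
            def __init__(self, cid, mol, pki):
                self.compound_id, self.canonical_smiles, self.pki = (
                    cid, Chem.MolToSmiles(mol), pki)

        index = structure_index([
            C("lo", lo, 6.0), C("hi", hi, 8.0), C("h1", hy1, 6.9), C("h2", hy2, 7.2),
        ])
        matches = find_single_site_analogs(dual_cliff(2.0), index)
        assert {(m.site_index, m.analog_id) for m in matches} == {(1, "h1"), (2, "h2")}
        assert [m.delta_single for m in matches] == pytest.approx([0.9, 1.2])

    def test_absent_hybrids_yield_no_matches(self):
        lo = weld(CORE, ["*C", "*C"])
        hi = weld(CORE, ["*CC", "*CCC"])

        class C:
            def __init__(self, cid, mol, pki):
                self.compound_id, self.canonical_smiles, self.pki = (
                    cid, Chem.MolToSmiles(mol), pki)

        index = structure_index([C("lo", lo, 6.0), C("hi", hi, 8.0)])
        assert find_single_site_analogs(dual_cliff(2.0), index) == []

    def test_swap_is_an_involution(self):
        """Swapping one site to the partner's substituent and back returns
        the original compound."""
        lo_subs = ["*C", "*C"]
        hi_subs = ["*CC", "*CCC"]
        lo = Chem.MolToSmiles(weld(CORE, lo_subs))
        once = list(lo_subs)
        once[0] = hi_subs[0]
        back = list(once)
        back[0] = lo_subs[0]
        assert Chem.MolToSmiles(weld(CORE, back)) == lo
        assert Chem.MolToSmiles(weld(CORE, once)) != lo


class TestOnFixtures:
    def test_exact_additive_potencies_classify_additive(self, additive_run):
        out, _ = additive_run
        summary = json.loads((out / "summary.json").read_text())
        tallies = summary["targets"]["FTADD"]["decomposition"]
        assert tallies["both_matches"] > 0
        assert tallies["additive"] == tallies["both_matches"]
        assert tallies["synergistic"] == tallies["compensatory"] == 0

    def test_planted_synergy_is_detected(self, synergy_run):
        out, _ = synergy_run
        summary = json.loads((out / "summary.json").read_text())
        tallies = summary["targets"]["FTSYN"]["decomposition"]
        assert tallies["both_matches"] > 0
        assert tallies["synergistic"] == tallies["both_matches"]

    def test_dominant_substitution_is_detected(self, dominant_run):
        """The designed cliff carries 95% of its Δ in one substitution and
        both hybrids are measured: it must come out determined_by_one."""
        import pandas as pd

        out, truth = dominant_run
        rows = pd.read_csv(out / "decomposition.tsv", sep="\t")
        t = truth["targets"]["FTDOM"]
        # the fully decomposable designed cliff: base compound vs. the
        # double-substituted extra member (largest Δ in the set)
        designed = rows[rows.delta_dual == rows.delta_dual.max()]
        assert set(designed.pattern) == {"determined_by_one"}
        assert len(designed) == 2  # both hybrid analogs were found
        assert designed.delta_single.max() == pytest.approx(
            0.95 * designed.delta_dual.iloc[0], abs=1e-6)
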