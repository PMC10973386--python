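import numpy as np
import pytest

from mipscan.module_caller import (
    ModuleCall,
    ModuleCallerConfig,
    assign_family,
    call_modules,
    call_nwe_module,
    call_repeat_array,
    call_snyg_module,
)
from mipscan.patterns import MotifMatch

from conftest import make_record


def _match(name, start, end, sid="p1", text=None):
    return MotifMatch(sid, name, start, end, text or "A" * (end - start + 1))


class TestNweModule:
    def test_triad_called_within_span(self):
        nwe = [_match("NWE", 10, 17)]
        mn = [_match("MN_UNIT", 30, 36), _match("MN_UNIT", 60, 66)]
        calls = call_nwe_module(nwe, mn)
        assert len(calls) == 1
        assert calls[0].module_type == "NWE_TRIAD"
        assert calls[0].region == (10, 66)
        starts = [m.start for m in calls[0].component_matches]
        assert starts == sorted(starts)  # NWE < Mn1 < Mn2

    def test_bare_motif_without_mn(self):
        calls = call_nwe_module([_match("NWE", 10, 17)], [])
        assert [c.module_type for c in calls] == ["NWE_ONLY"]

    def test_span_rule_rejects_distant_mn(self):
        nwe = [_match("NWE", 10, 17)]
        mn = [_match("MN_UNIT", 150, 156), _match("MN_UNIT", 160, 166)]
        calls = call_nwe_module(nwe, mn, max_module_span=100)
        assert [c.module_type for c in calls] == ["NWE_ONLY"]

    def test_mn_units_not_shared_between_triads(self):
        nwe = [_match("NWE", 1, 8), _match("NWE", 40, 47)]
        mn = [_match("MN_UNIT", 15, 21), _match("MN_UNIT", 28, 34),
              _match("MN_UNIT", 55, 61), _match("MN_UNIT", 70, 76)]
        calls = call_nwe_module(nwe, mn)
        assert [c.module_type for c in calls] == ["NWE_TRIAD", "NWE_TRIAD"]
        used = [m for c in calls for m in c.component_matches[1:]]
        assert len(set(used)) == 4


class TestRepeatArray:
    def test_chain_of_three(self):
        pyg = [_match("PYG", s, s + 4) for s in (10, 45, 80)]
        calls = call_repeat_array(pyg, min_copies=2, max_inter_gap=60)
        assert len(calls) == 1
        assert calls[0].module_type == "PYG_ARRAY"
        assert calls[0].copy_count == 3

    def test_singleton_yields_no_array(self):
        assert call_repeat_array([_match("GFG", 5, 7)], min_copies=2) == []

    def test_gfg_array_mean_spacing(self):
        gfg = [_match("GFG", s, s + 2) for s in (1, 32, 63, 94)]
        calls = call_repeat_array(gfg, min_copies=2, max_inter_gap=60)
        assert len(calls) == 1 and calls[0].copy_count == 4
        starts = [m.start for m in calls[0].component_matches]
        spacings = np.diff(starts)
        assert np.mean(spacings) == pytest.approx(31.0)

    def test_large_gap_splits_chains(self):
        mn = [_match("MN_UNIT", s, s + 6) for s in (1, 20, 200, 220)]
        calls = call_repeat_array(mn, min_copies=2, max_inter_gap=60)
        assert len(calls) == 2
        assert all(c.module_type == "MN_ARRAY" and c.copy_count == 2 for c in calls)


class TestSnygModule:
    def test_hydrophobic_flanks_promote(self):
        seq = make_record("AAAALLVLTNAAIGILLVAAAA")
        snyg = [_match("SNYG", 9, 14, text="TNAAIG")]
        calls = call_snyg_module(snyg, seq, flank_window=4, hydropathy_threshold=1.5)
        assert [c.module_type for c in calls] == ["SNYG_MODULE"]

    def test_charged_flanks_stay_candidate(self):
        seq = make_record("AAAADEDETNAAIGKRKRAAAA")
        snyg = [_match("SNYG", 9, 14, text="TNAAIG")]
        calls = call_snyg_module(snyg, seq, flank_window=4, hydropathy_threshold=1.5)
        assert [c.module_type for c in calls] == ["SNYG_CANDIDATE"]

    def test_truncated_flank_flagged(self):
        seq = make_record("ATNAAIGILLVAAAA")
        snyg = [_match("SNYG", 2, 7, text="TNAAIG")]
        calls = call_snyg_module(snyg, seq, flank_window=4)
        assert calls[0].flags == ("truncated_flank",)


class TestAssignFamily:
    def _call(self, mtype, lo=1, hi=10):
        return ModuleCall("p1", mtype, (lo, hi))

    @pytest.mark.parametrize(
        "types,expected",
        [
            (["NWE_TRIAD"], "NWE + Mn"),
            (["NWE_ONLY"], "NWE only"),
            (["MN_ARRAY"], "Mn repeat (only)"),
            (["MN_ARRAY", "PYG_ARRAY"], "Mn + PYG"),
            (["PYG_ARRAY"], "PYG"),
            (["GFG_ARRAY"], "GFG repeat"),
            (["SNYG_MODULE"], "SNYG"),
            (["ELLEN"], "ELLEn"),
            ([], "unassigned"),
            (["MN_UNIT_ISOLATED"], "unassigned"),
            (["SNYG_CANDIDATE"], "unassigned"),
        ],
    )
    def test_precedence_labels(self, types, expected):
        calls = [self._call(t, 1 + 20 * i, 10 + 20 * i) for i, t in enumerate(types)]
        assert assign_family(calls, "p1").family_label == expected

    def test_order_independence(self):
        rng = np.random.default_rng(0)
        calls = [self._call(t, 1 + 20 * i, 10 + 20 * i)
                 for i, t in enumerate(["NWE_TRIAD", "MN_ARRAY", "PYG_ARRAY", "SNYG_MODULE"])]
        labels = set()
        for _ in range(10):
            perm = [calls[j] for j in rng.permutation(len(calls))]
            fa = assign_family(perm, "p1")
            labels.add((fa.family_label, fa.secondary_labels))
        assert len(labels) == 1

    def test_secondary_labels_listed(self):
        calls = [self._call("NWE_TRIAD", 1, 60), self._call("GFG_ARRAY", 100, 160)]
        fa = assign_family(calls, "p1")
        assert fa.family_label == "NWE + Mn"
        assert "GFG repeat" in fa.secondary_labels


class TestCallModulesPipeline:
    def test_component_matches_exist_in_scan_output(self, registry):
        # NWE motif + two Mn units within 100 residues
        seq = make_record(
            "A" * 10 + "LLIGNWAE" + "A" * 12 + "TTAAAAY" + "A" * 9 + "TTAAAAY" + "A" * 20,
            "nwe_prot",
        )
        calls, fam = call_modules(seq, registry)
        from mipscan.patterns import scan
        all_matches = {
            m for p in registry.values() for m in scan(seq, p, mode="leftmost-nonoverlapping")
        }
        for c in calls:
            for m in c.component_matches:
                assert m in all_matches
        assert fam.family_label == "NWE + Mn"

    def test_region_covers_components_enforced(self):
        with pytest.raises(ValueError, match="cover"):
            ModuleCall("p1", "ELLEN", (5, 10),
                       component_matches=(_match("ELLEN", 1, 20),))
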