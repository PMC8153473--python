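import pytest

from gatafam.variation import (GAP_STATE, ResidueState, StructureTrack,
                               align_ortholog_domains,
                               build_variation_matrix,
                               classify_position_context,
                               count_multiform_tfs,
                               heterozygosity_by_subfamily, property_change,
                               trim_trailing_overhang)
from _oracles import oracle_align3


def S(residue, codon=""):
    return ResidueState.from_residue(residue, codon)


def row(seq):
    return [S(c) for c in seq]


def consensus_strings(msa):
    return {k: "".join("-" if s.is_gap else s.consensus for s in v)
            for k, v in msa.items()}


class TestAlignment:
    def test_identical_sequences_identity_mapping(self):
        seq = "CAYCAEFGHIKLMNPQRSTVWYKRCACK" * 2
        msa = align_ortholog_domains({"e1": seq, "e2": seq, "e3": seq})
        assert consensus_strings(msa) == {e: seq for e in ("e1", "e2", "e3")}

    def test_equal_length_with_few_mismatches_stays_gapless(self):
        a = "MKWCDEFGHIKLNPQRSTVW"
        b = a[:5] + "A" + a[6:]
        msa = align_ortholog_domains({"x": a, "y": b})
        assert consensus_strings(msa) == {"x": a, "y": b}

    def test_two_residue_deletion_gets_gap_columns(self):
        base = "MKWCDEFGHIKLNPQRSTVWYAE"
        short = base[:10] + base[12:]      # drop K, L
        msa = align_ortholog_domains({"e1": base, "e2": base, "e3": short})
        strs = consensus_strings(msa)
        assert strs["e1"] == base
        assert strs["e3"].count("-") == 2
        assert len(strs["e3"]) == len(base)

    def test_matches_exhaustive_three_way_alignment(self):
        base = "MKWCDEFGHIRLNPQSTVWYAE"
        short = base[:8] + base[10:]
        msa = align_ortholog_domains({"a": base, "b": base, "c": short})
        got = list(zip(*(consensus_strings(msa)[k] for k in "abc")))
        expected = oracle_align3(base, base, short)
        assert got == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_ortholog_domains({})

    def test_trailing_overhang_trimmed(self):
        msa = {"e1": row("MKWC") + [GAP_STATE],
               "e2": row("MKWC") + [GAP_STATE],
               "e3": row("MKWCE")}
        trimmed = trim_trailing_overhang(msa)
        assert all(len(v) == 4 for v in trimmed.values())


class TestVariationMatrix:
    def _vm(self):
        msas = {
            # one substitution in e2 -> variable
            "T1.a": {"e1": row("MKWC"), "e2": row("MKAC"), "e3": row("MKWC")},
            # heterozygous {C,G} vs {C} -> variable and heterozygous
            "T2.a": {"e1": [ResidueState(frozenset("CG"), "KGT")] + row("AAA"),
                     "e2": row("CAAA"), "e3": row("CAAA")},
            # ambiguity that never changes the residue -> silent, NOT variable
            "T3.a": {"e1": row("GLLL"), "e2": [S("G", "GGM")] + row("LLL"),
                     "e3": row("GLLL")},
            # single-ecotype TF: excluded from the totals
            "T4.b": {"e1": row("MMMM")},
        }
        return build_variation_matrix(msas)

    def test_variable_and_silent_positions(self):
        vm = self._vm()
        assert vm.per_tf["T1.a"].variable_positions == [3]
        assert vm.per_tf["T2.a"].variable_positions == [1]
        assert vm.per_tf["T2.a"].msa["e1"][0].heterozygous
        assert vm.per_tf["T3.a"].variable_positions == []
        assert vm.per_tf["T3.a"].silent_het_positions == [1]

    def test_totals_exclude_single_ecotype_tfs(self):
        vm = self._vm()
        assert vm.n_total_positions == 12
        assert vm.n_variable_positions == 2

    def test_n_forms_counts_distinct_rows(self):
        vm = self._vm()
        assert vm.per_tf["T1.a"].n_forms == 2
        assert vm.per_tf["T2.a"].n_forms == 2   # {C/G} differs from C
        assert vm.per_tf["T3.a"].n_forms == 1   # silent ambiguity is no form

    def test_row_order_invariance(self):
        msa = {"e1": row("MKWC"), "e2": row("MKAC"), "e3": row("MKWC")}
        a = build_variation_matrix({"T.a": msa})
        b = build_variation_matrix(
            {"T.a": {k: msa[k] for k in ("e3", "e1", "e2")}})
        assert a.per_tf["T.a"].variable_positions == \
            b.per_tf["T.a"].variable_positions
        assert a.per_tf["T.a"].n_forms == b.per_tf["T.a"].n_forms

    def test_ragged_msa_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_variation_matrix(
                {"T.a": {"e1": row("MK"), "e2": row("MKW")}})

    def test_percentage_rounding(self):
        # 22 variable out of 2195 columns must print as 1.002
        msas = {}
        for i in range(439):
            seq = "MKWCA"
            alt = "MKWCG" if i < 22 else seq
            msas[f"T{i}.a"] = {"e1": row(seq), "e2": row(alt)}
        vm = build_variation_matrix(msas)
        assert vm.n_total_positions == 2195
        assert vm.n_variable_positions == 22
        assert vm.pct_variable == 1.002

    def test_multiform_percentage(self):
        msas = {}
        for i in range(43):
            alt = "MA" if i < 13 else "MK"
            msas[f"T{i}.a"] = {"e1": row("MK"), "e2": row(alt)}
        assert count_multiform_tfs(build_variation_matrix(msas)) == \
            (13, 43, 30.23)


class TestContextAndGroups:
    def test_position_context_tally(self):
        track = StructureTrack.from_segments([("alpha_helix", 2, 3)], 6)
        msas = {"T.a": {"e1": row("MKWCAA"), "e2": row("MAWCAG")}}
        vm = build_variation_matrix(msas)
        assert vm.per_tf["T.a"].variable_positions == [2, 6]
        assert classify_position_context(vm, track) == (1, 1)

    def test_track_shorter_than_domain_rejected(self):
        track = StructureTrack.from_segments([], 2)
        vm = build_variation_matrix(
            {"T.a": {"e1": row("MKW"), "e2": row("MAW")}})
        with pytest.raises(ValueError, match="shorter"):
            classify_position_context(vm, track)

    @pytest.mark.parametrize("a,b,expected", [
        ("R", "K", "same_group"),       # both electrically charged
        ("I", "T", "different_group"),  # hydrophobic vs polar uncharged
        ("A", "A", "same_group"),
    ])
    def test_property_change(self, a, b, expected):
        assert property_change(a, b) == expected

    def test_property_change_rejects_gap(self):
        with pytest.raises(ValueError):
            property_change("-", "A")

    def test_heterozygosity_by_subfamily(self):
        msas = {
            "T1.a": {"e1": row("MK"), "e2": row("MA")},
            "T2.a": {"e1": row("QQ"), "e2": row("QQ")},
        }
        vm = build_variation_matrix(msas)
        out = heterozygosity_by_subfamily(vm, {"T1.a": "I", "T2.a": "II"})
        assert out["I"] == (1, 50.0)
        assert out["II"] == (0, 0.0)

    def test_unmapped_tf_rejected(self):
        vm = build_variation_matrix({"T.a": {"e1": row("M"), "e2": row("M")}})
        with pytest.raises(KeyError):
            heterozygosity_by_subfamily(vm, {})


class TestPanelRecovery:
    def test_variation_totals(self, result, truth):
        exp = truth["variation"]
        assert result.vm.n_variable_positions == exp["n_variable_positions"]
        assert result.vm.n_total_positions == exp["n_total_columns"]
        assert result.vm.pct_variable == 1.002

    def test_planted_variant_recovery_is_exact(self, result, truth):
        multi = sorted(tf for tf, b in result.vm.per_tf.items()
                       if b.n_forms >= 2)
        assert multi == truth["variation"]["multiform_tfs"]

    def test_silent_het_sites_listed_not_counted(self, result, truth):
        n_silent = sum(len(b.silent_het_positions)
                       for b in result.vm.per_tf.values())
        assert n_silent == truth["variation"]["n_silent_het_sites"]

    def test_heterozygosity_by_subfamily_matches_plan(self, result, truth):
        out = heterozygosity_by_subfamily(result.vm, result.subfamily_of_tf)
        for sf, expected in truth["variation"]["by_subfamily"].items():
            assert out[sf][0] == expected
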