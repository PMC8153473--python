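import numpy as np
import pandas as pd
import pytest

from gatafam.domain_scan import DomainHit
from gatafam.family_census import (EcotypeCensus, SubfamilyRef,
                                   assign_subfamily, build_census,
                                   group_distribution_types, pan_isoform_set,
                                   subfamily_ratios, unique_isoforms)


def _hit(domain_seq, dtype="IV_b"):
    return DomainHit("p", 1, len(domain_seq), 26, (2, 18, 2), dtype,
                     domain_seq)


@pytest.fixture(scope="module")
def refs(panel):
    return panel.refs


class TestAssignSubfamily:
    def test_iv_c_goes_to_iii(self, refs):
        hit = _hit(refs[0].domain_seq, dtype="IV_c")
        assert assign_subfamily(hit, refs) == "III"

    def test_accessory_domains_force_iii(self, refs):
        hit = _hit(refs[0].domain_seq)
        assert assign_subfamily(hit, refs, {"TIFY", "CCT"}) == "III"

    def test_identical_to_reference(self, refs):
        for ref in refs:
            if ref.subfamily == "III":
                continue
            hit = _hit(ref.domain_seq)
            assert assign_subfamily(hit, refs) == ref.subfamily

    def test_nearest_reference_wins(self, refs):
        ref_ii = next(r for r in refs if r.subfamily == "II")
        seq = list(ref_ii.domain_seq)
        seq[10], seq[15] = "W", "W"   # 2 mutations from the II reference
        assert assign_subfamily(_hit("".join(seq)), refs) == "II"

    def test_empty_refs_rejected(self):
        with pytest.raises(ValueError):
            assign_subfamily(_hit("CAAC"), [])

    def test_missing_subfamily_rejected(self, refs):
        with pytest.raises(ValueError, match="missing"):
            assign_subfamily(_hit("CAAC"), refs[:2])


def _table(n_genes, n_isoforms, subfamily="I"):
    """TF table with the first genes carrying the extra isoforms."""
    rows = []
    extra = n_isoforms - n_genes
    for i in range(n_genes):
        labels = ["a", "b"] if i < extra else ["a"]
        for lab in labels:
            rows.append({"gene_id": f"g{i}", "ortholog_key": f"G{i}",
                         "tx_id": f"g{i}.{lab}", "isoform_label": lab,
                         "subfamily": subfamily, "has_domain": True})
    return pd.DataFrame(rows)


class TestCensus:
    @pytest.mark.parametrize("genes,isoforms,avg", [
        (30, 42, 1.40),
        (29, 39, 1.34),
        (1, 1, 1.00),
    ])
    def test_avg_as(self, genes, isoforms, avg):
        c = build_census("e", _table(genes, isoforms))
        assert (c.n_genes, c.n_tfs, c.avg_as) == (genes, isoforms, avg)

    def test_as_counts(self):
        c = build_census("e", _table(30, 42))
        assert c.n_genes_with_as == 12 and c.n_as_forms == 24

    def test_domainless_isoforms_not_counted(self):
        t = _table(3, 4)
        t.loc[len(t)] = {"gene_id": "g0", "ortholog_key": "G0",
                         "tx_id": "g0.c", "isoform_label": "c",
                         "subfamily": "", "has_domain": False}
        c = build_census("e", t)
        assert (c.n_genes, c.n_tfs) == (3, 4)

    def test_duplicate_tx_rejected(self):
        t = pd.concat([_table(2, 2)] * 2)
        with pytest.raises(ValueError, match="duplicate"):
            build_census("e", t)

    def test_presence_vector_against_universe(self):
        c = build_census("e", _table(2, 2), ortholog_keys=["G0", "G1", "G9"])
        assert c.presence == {"G0": True, "G1": True, "G9": False}


class TestRatios:
    @pytest.mark.parametrize("genes,tfs,expected", [
        (3, 7, 2.33), (2, 5, 2.50), (14, 19, 1.36), (11, 12, 1.09),
    ])
    def test_rounding(self, genes, tfs, expected):
        c = EcotypeCensus("e", genes, tfs, {"III": (genes, tfs)}, 0, 0)
        assert subfamily_ratios(c)["III"] == expected

    def test_empty_subfamily_undefined(self):
        c = EcotypeCensus("e", 0, 0, {"IV": (0, 0)}, 0, 0)
        assert subfamily_ratios(c)["IV"] is None


class TestDistributionTypes:
    def _census(self, eco, sig_iii):
        return EcotypeCensus(eco, 30, 41,
                             {"I": (14, 19), "II": (11, 11),
                              "III": sig_iii, "IV": (2, 4)}, 9, 20)

    def test_partition_and_ordering(self):
        censuses = ([self._census(f"e{i}", (3, 7)) for i in range(5)]
                    + [self._census(f"x{i}", (2, 5)) for i in range(2)]
                    + [self._census("solo", (3, 8))])
        types = group_distribution_types(censuses)
        assert [len(t.member_ecotypes) for t in types] == [5, 2, 1]
        assert [t.type_label for t in types] == [1, 2, 3]

    def test_invariant_to_input_order(self):
        censuses = [self._census(f"e{i}", (3, 7) if i % 2 else (2, 5))
                    for i in range(6)]
        rng = np.random.default_rng(3)
        a = group_distribution_types(censuses)
        shuffled = list(censuses)
        rng.shuffle(shuffled)
        b = group_distribution_types(shuffled)
        assert [(t.type_label, t.member_ecotypes) for t in a] == \
            [(t.type_label, t.member_ecotypes) for t in b]

    def test_all_identical_single_type(self):
        types = group_distribution_types(
            [self._census(f"e{i}", (3, 7)) for i in range(4)])
        assert len(types) == 1


class TestPanIsoforms:
    def test_unique_isoform_flagged(self):
        t1, t2 = _table(2, 3), _table(2, 2)
        distinct, mat = pan_isoform_set({"e1": t1, "e2": t2})
        assert ("G0", "b") in distinct
        assert unique_isoforms(mat) == {"e1": ["G0.b"], "e2": []}

    def test_identical_panels(self):
        t = _table(3, 4)
        distinct, mat = pan_isoform_set({"e1": t, "e2": t.copy()})
        assert len(distinct) == 4 and (mat.values == 1).all()


class TestPanelRecovery:
    def test_census_totals_match_ground_truth(self, result, truth):
        for eco, c in result.censuses.items():
            exp = truth["per_ecotype"][eco]
            assert c.n_genes == exp["n_genes"]
            assert c.n_tfs == exp["n_tfs"]
            assert c.n_genes_with_as == exp["n_genes_with_as"]
            assert c.n_as_forms == exp["n_as_forms"]
            for sf, (g, t) in c.per_subfamily.items():
                assert (g, t) == tuple(exp["per_subfamily"][sf])

    def test_distribution_types_match_plan(self, result, truth):
        assert [sorted(t.member_ecotypes) for t in result.types] == \
            truth["type_members"]

    def test_unique_isoforms_recovered(self, result, truth):
        uniques = unique_isoforms(result.presence)
        expected = truth["unique_isoforms"]
        assert {e: v for e, v in uniques.items() if v} == expected
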