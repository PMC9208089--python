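"""Record labeling, pair voting, family labeling and selection rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panmoiety.catalog import CatalogEntry, FamilyCatalog, read_catalog_csv, write_catalog_csv
from panmoiety.curation import (
    BioactivityRecord,
    build_kinase_sets,
    chembl_prefilter,
    label_family_inhibitors,
    label_record,
    read_bioactivity_table,
    select_families,
    summarize_families,
    summary_from_counts,
    vote_all_pairs,
    vote_pair,
    write_bioactivity_csv,
)


def rec(value, assay="IC50", compound="C1", kinase="K1"):
    return BioactivityRecord(compound, kinase, assay, value)


class TestRecordLabeling:
    @pytest.mark.parametrize(
        "assay,value,expected",
        [
            ("IC50", 400.0, True),
            ("IC50", 499.999, True),
            ("IC50", 500.0, False),  # strict boundary
            ("IC50", 20000.0, False),
            ("pKi", 6.3, False),  # strict boundary
            ("pKi", 7.0, True),
            ("pKi", 4.0, False),
        ],
    )
    def test_threshold_rules(self, assay, value, expected):
        assert label_record(rec(value, assay)) is expected

    def test_unknown_assay_rejected(self):
        with pytest.raises(ValueError, match="assay_type"):
            BioactivityRecord("C1", "K1", "Kd", 10.0)

    def test_nonpositive_ic50_rejected(self):
        with pytest.raises(ValueError):
            BioactivityRecord("C1", "K1", "IC50", -5.0)


class TestPairVoting:
    def test_all_positive_is_active(self):
        call = vote_pair([rec(100.0)] * 3)
        assert call.call == "active" and call.positive_fraction == 1.0

    def test_all_negative_is_inactive(self):
        call = vote_pair([rec(5000.0)] * 5)
        assert call.call == "inactive" and call.positive_fraction == 0.0

    def test_exactly_eighty_percent_is_ambiguous(self):
        call = vote_pair([rec(100.0)] * 4 + [rec(5000.0)])
        assert call.call == "ambiguous" and call.positive_fraction == 0.8

    def test_exactly_twenty_percent_is_ambiguous(self):
        call = vote_pair([rec(100.0)] + [rec(5000.0)] * 4)
        assert call.call == "ambiguous"

    def test_mixed_units_vote_together(self):
        # one positive pKi + one negative IC50: fraction 0.5 -> ambiguous
        call = vote_pair([rec(8.0, "pKi"), rec(5000.0)])
        assert call.call == "ambiguous" and call.n_records == 2

    def test_empty_and_mixed_pairs_rejected(self):
        with pytest.raises(ValueError):
            vote_pair([])
        with pytest.raises(ValueError, match="multiple pairs"):
            vote_pair([rec(100.0, kinase="K1"), rec(100.0, kinase="K2")])

    @given(
        n_pos=st.integers(0, 12),
        n_neg=st.integers(0, 12),
        perm_seed=st.integers(0, 1000),
    )
    @settings(max_examples=60, deadline=None)
    def test_vote_is_order_invariant(self, n_pos, n_neg, perm_seed):
        if n_pos + n_neg == 0:
            return
        records = [rec(100.0)] * n_pos + [rec(5000.0)] * n_neg
        shuffled = list(np.random.default_rng(perm_seed).permutation(len(records)))
        assert vote_pair(records).call == vote_pair([records[i] for i in shuffled]).call

    @given(n_pos=st.integers(0, 10), n_neg=st.integers(0, 10))
    @settings(max_examples=60, deadline=None)
    def test_adding_positive_never_demotes(self, n_pos, n_neg):
        if n_pos + n_neg == 0:
            return
        order = {"inactive": 0, "ambiguous": 1, "active": 2}
        before = vote_pair([rec(100.0)] * n_pos + [rec(5000.0)] * n_neg)
        after = vote_pair([rec(100.0)] * (n_pos + 1) + [rec(5000.0)] * n_neg)
        assert order[after.call] >= order[before.call]


class TestKinaseSets:
    def test_single_calls(self):
        active = vote_pair([rec(100.0)])
        sets = build_kinase_sets([active])
        assert sets["K1"] == ({"C1"}, set())
        ambiguous = vote_pair([rec(100.0)] * 4 + [rec(5000.0)])
        assert build_kinase_sets([ambiguous])["K1"] == (set(), set())

    def test_two_kinases_two_keys(self):
        calls = [vote_pair([rec(100.0, kinase=k)]) for k in ("K1", "K2")]
        assert set(build_kinase_sets(calls)) == {"K1", "K2"}

    def test_duplicate_pair_rejected(self):
        call = vote_pair([rec(100.0)])
        with pytest.raises(ValueError, match="duplicate"):
            build_kinase_sets([call, call])


def make_catalog(m_f, structures=None):
    members = tuple(f"K{i}" for i in range(m_f))
    structures = structures or tuple(True for _ in members)
    return FamilyCatalog([CatalogEntry("G", "FAM", members, structures)])


def sets_for(active_on, inactive_on):
    sets = {}
    for k in active_on:
        sets.setdefault(k, (set(), set()))[0].add("C1")
    for k in inactive_on:
        sets.setdefault(k, (set(), set()))[1].add("C1")
    return sets


class TestFamilyLabeling:
    @pytest.mark.parametrize(
        "m_f,active_on,inactive_on,expected",
        [
            (4, ["K0", "K1"], [], 1),  # half of four members
            (4, ["K0"], ["K1"], 0),  # below half
            (3, ["K0", "K1"], [], 1),  # ceil(3/2)=2
            (3, ["K0"], ["K1"], 0),  # 1 of 3 is less than half
            (2, ["K0"], ["K1"], 1),  # 1 of 2 is exactly half
            (2, [], ["K0", "K1"], 0),
        ],
    )
    def test_half_of_members_rule(self, m_f, active_on, inactive_on, expected):
        datasets = label_family_inhibitors(sets_for(active_on, inactive_on), make_catalog(m_f))
        assert datasets[0].compound_ids == ["C1"]
        assert datasets[0].labels[0] == expected

    def test_floor_threshold_option(self):
        sets = sets_for(["K0"], ["K1"])
        ceil_ds = label_family_inhibitors(sets, make_catalog(3), family_threshold="ceil")
        floor_ds = label_family_inhibitors(sets, make_catalog(3), family_threshold="floor")
        assert ceil_ds[0].labels[0] == 0 and floor_ds[0].labels[0] == 1

    def test_untested_members_count_as_not_inhibited(self):
        # active on 1 member of 4, others untested: below half
        datasets = label_family_inhibitors(sets_for(["K0"], []), make_catalog(4))
        assert datasets[0].labels[0] == 0

    def test_unknown_kinase_is_skipped_with_warning(self, caplog):
        sets = sets_for(["K0"], [])
        sets["K_ALIEN"] = ({"C9"}, set())
        with caplog.at_level("WARNING"):
            datasets = label_family_inhibitors(sets, make_catalog(2))
        assert "K_ALIEN" in caplog.text
        assert "C9" not in datasets[0].compound_ids

    def test_inactive_scope_all_includes_untested_compounds(self):
        catalog = FamilyCatalog(
            [
                CatalogEntry("G", "F1", ("K0",), (True,)),
                CatalogEntry("G", "F2", ("K1",), (True,)),
            ]
        )
        sets = {"K0": ({"C1"}, set()), "K1": ({"C2"}, set())}
        tested = label_family_inhibitors(sets, catalog, inactive_scope="tested")
        assert tested[0].compound_ids == ["C1"]
        everything = label_family_inhibitors(sets, catalog, inactive_scope="all")
        assert everything[0].compound_ids == ["C1", "C2"]
        assert list(everything[0].labels) == [1, 0]

    def test_active_inactive_partition(self, saturated_world):
        catalog, _, records = saturated_world
        datasets = label_family_inhibitors(
            build_kinase_sets(vote_all_pairs(records)), catalog
        )
        for ds in datasets:
            active = {c for c, l in zip(ds.compound_ids, ds.labels) if l == 1}
            inactive = {c for c, l in zip(ds.compound_ids, ds.labels) if l == 0}
            assert active.isdisjoint(inactive)
            assert active | inactive == set(ds.compound_ids)


class TestFamilySelection:
    def _dataset(self, n_active, n_inactive, m_f=2, structures=None):
        entry = make_catalog(m_f, structures).entries[0]
        n = n_active + n_inactive
        ids = [f"C{i}" for i in range(n)]
        labels = np.array([1] * n_active + [0] * n_inactive)
        from panmoiety.curation import FamilyDataset

        return FamilyDataset(entry, ids, labels)

    def test_size_threshold(self):
        small = self._dataset(125, 124)
        exact = self._dataset(125, 125)
        assert select_families([small]) == []
        assert select_families([exact]) == [exact]

    def test_structure_requirement(self):
        ds = self._dataset(200, 100, structures=(False, False))
        assert select_families([ds], require_structure=True) == []
        assert select_families([ds], require_structure=False) == [ds]

    def test_min_kinases(self):
        entry = CatalogEntry("G", "FAM", ("K0",), (True,))
        from panmoiety.curation import FamilyDataset

        ds = FamilyDataset(entry, ["C0"] * 0 + [f"C{i}" for i in range(300)],
                           np.ones(300, dtype=int))
        assert select_families([ds], min_kinases=2) == []


class TestSummaries:
    def test_printed_family_rows(self):
        # group, family, M_f, active, inactive
        table = summary_from_counts(
            [
                ("TK", "EGFR", 4, 692, 809),
                ("AGC", "Akt", 3, 401, 774),
            ]
        )
        egfr = table.iloc[0]
        assert egfr.total == 1501 and egfr.ratio == 0.86
        akt = table.iloc[1]
        assert akt.total == 1175 and akt.ratio == 0.52

    def test_degenerate_ratios(self):
        table = summary_from_counts([("G", "A", 2, 0, 5), ("G", "B", 2, 5, 0)])
        assert table.iloc[0].ratio == 0.0
        assert math.isinf(table.iloc[1].ratio)

    def test_summarize_matches_counts(self, saturated_world):
        catalog, _, records = saturated_world
        datasets = label_family_inhibitors(
            build_kinase_sets(vote_all_pairs(records)), catalog
        )
        table = summarize_families(datasets)
        assert (table["total"] == table["n_active"] + table["n_inactive"]).all()
        assert len(table) == len(datasets)


class TestIO:
    def test_bioactivity_round_trip(self, tmp_path, saturated_world):
        _, _, records = saturated_world
        path = tmp_path / "bio.csv"
        write_bioactivity_csv(records, path)
        back = read_bioactivity_table(path)
        assert back == records

    def test_catalog_round_trip(self, tmp_path, saturated_world):
        catalog, _, _ = saturated_world
        path = tmp_path / "cat.csv"
        write_catalog_csv(catalog, path)
        back = read_catalog_csv(path)
        assert back.families == catalog.families
        assert back.kinase_ids == catalog.kinase_ids

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("compound_id,value\nC1,5\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_bioactivity_table(p)

    def test_chembl_prefilter_drops_low_confidence(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "compound_id": ["C1", "C2", "C3"],
                "standard_relation": ["=", ">", "="],
                "confidence_score": [9, 9, 5],
            }
        )
        kept = chembl_prefilter(df)
        assert list(kept["compound_id"]) == ["C1"]
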