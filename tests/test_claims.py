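"""ICD-10 cause grouping, count summaries, demographic strata."""

import numpy as np
import pandas as pd
import pytest

from heatlagccx.claims import (age_group, assign_stratum, assign_strata,
                               classify_visit, classify_visits,
                               heat_related_shares, load_cause_groups,
                               percent_of_allcause, read_visits,
                               summarize_counts)

# printed counts of the study's Table 1 (used as fixed inputs)
TABLE1_COUNTS = {
    "all_cause": 1188438,
    "infectious_parasitic": 48472,
    "bacterial_enteritis": 7111,
    "blood_immune": 4550,
    "endocrine_metabolic": 4521,
    "mental_behavioral": 26366,
    "nervous_system": 16309,
    "otitis_media_externa": 48245,
    "cardiovascular": 5699,
    "respiratory": 157927,
    "asthma": 21754,
    "digestive": 56498,
    "skin_soft_tissue_infections": 24458,
    "other_skin_soft_tissue": 24699,
    "musculoskeletal": 42181,
    "genitourinary": 34000,
    "perinatal": 9026,
    "signs_symptoms": 268317,
    "suicidality_depression": 16579,
    "injury_poisoning": 467762,
    "heat_related": 25362,
    "external_causes": 25835,
}
TABLE1_PERCENTS = {
    "infectious_parasitic": 4.08, "bacterial_enteritis": 0.60,
    "blood_immune": 0.38, "endocrine_metabolic": 0.38,
    "mental_behavioral": 2.22, "nervous_system": 1.37,
    "otitis_media_externa": 4.06, "cardiovascular": 0.48,
    "respiratory": 13.29, "asthma": 1.83, "digestive": 4.75,
    "skin_soft_tissue_infections": 2.06, "other_skin_soft_tissue": 2.08,
    "musculoskeletal": 3.55, "genitourinary": 2.86, "perinatal": 0.76,
    "signs_symptoms": 22.58, "suicidality_depression": 1.40,
    "injury_poisoning": 39.36, "heat_related": 2.13, "external_causes": 2.17,
}


class TestGroupTable:
    def test_group_inventory(self, cause_groups):
        names = [g.name for g in cause_groups]
        assert len(names) == 22 and len(set(names)) == 22
        assert "all_cause" in names

    def test_heat_group_is_only_any_mention(self, cause_groups):
        heat = [g for g in cause_groups if g.match_scope == "any_mention"]
        assert [g.name for g in heat] == ["heat_related"]
        starts = {s for s, _ in heat[0].ranges}
        assert starts == {"T67", "E86", "E87"}

    def test_injury_range_skips_heat_category(self, cause_groups):
        injury = next(g for g in cause_groups if g.name == "injury_poisoning")
        assert injury.contains("T66")
        assert injury.contains("T68")
        assert not injury.contains("T670XXA")

    def test_suicidality_codes(self, cause_groups):
        g = next(g for g in cause_groups if g.name == "suicidality_depression")
        for code in ("R4585", "R4586", "R4587", "R451", "R454", "R456",
                     "F329", "F330"):
            assert g.contains(code), code
        for code in ("R4588", "R450", "R457", "F319"):
            assert not g.contains(code), code

    def test_designated_overlap_groups(self, cause_groups):
        overlaps = {g.name for g in cause_groups if g.overlap}
        assert overlaps == {"asthma", "bacterial_enteritis",
                            "suicidality_depression"}


class TestClassifyVisit:
    def test_asthma_nested_in_respiratory(self, cause_groups):
        assert classify_visit("J45.41", [], cause_groups) == {
            "all_cause", "respiratory", "asthma"}

    def test_secondary_heat_code_any_mention(self, cause_groups):
        assert classify_visit("S93.4", ["T67.0"], cause_groups) == {
            "all_cause", "injury_poisoning", "heat_related"}

    def test_principal_t67_not_injury(self, cause_groups):
        assert classify_visit("T67.5", [], cause_groups) == {
            "all_cause", "heat_related"}

    def test_unparseable_code_allcause_only(self, cause_groups):
        assert classify_visit("??bad", [], cause_groups) == {"all_cause"}

    def test_order_independent_in_secondaries(self, cause_groups):
        a = classify_visit("R50.9", ["E86.0", "J45.0"], cause_groups)
        b = classify_visit("R50.9", ["J45.0", "E86.0"], cause_groups)
        assert a == b == {"all_cause", "signs_symptoms", "heat_related"}

    def test_vectorized_matches_scalar(self, cause_groups):
        visits = pd.DataFrame({
            "principal_dx": ["J45.41", "S93.4", "T67.5", "E86.9", "bad",
                             "A04.7", "R45.851", "E85.1"],
            "secondary_dx": [[], ["T67.0"], [], [], [], [], [], ["E87.0"]]})
        lab = classify_visits(visits, cause_groups)
        for i, row in visits.iterrows():
            expect = classify_visit(row["principal_dx"], row["secondary_dx"],
                                    cause_groups)
            got = {g.name for g in cause_groups if lab.loc[i, g.name]}
            assert got == expect, row["principal_dx"]

    def test_every_visit_in_allcause(self, cause_groups):
        lab = classify_visits(pd.DataFrame({
            "principal_dx": ["J45", "nonsense"],
            "secondary_dx": [[], []]}), cause_groups)
        assert lab["all_cause"].all()


class TestCounts:
    def test_printed_percent_column_reproduced(self):
        pct = percent_of_allcause(TABLE1_COUNTS)
        for name, expected in TABLE1_PERCENTS.items():
            assert pct[name] == pytest.approx(expected, abs=0.005), name

    def test_summarize_counts_from_labels(self, cause_groups):
        lab = classify_visits(pd.DataFrame({
            "principal_dx": ["T67.0", "J06.9", "J45.0", "S52.5"],
            "secondary_dx": [[], [], [], []]}), cause_groups)
        tab = summarize_counts(lab, cause_groups).set_index("group")
        assert tab.loc["all_cause", "n"] == 4
        assert tab.loc["respiratory", "n"] == 2
        assert tab.loc["heat_related", "percent"] == pytest.approx(25.0)

    def test_empty_input(self, cause_groups):
        lab = classify_visits(pd.DataFrame({"principal_dx": [],
                                            "secondary_dx": []}), cause_groups)
        tab = summarize_counts(lab, cause_groups)
        assert (tab["n"] == 0).all()

    def test_heat_shares_two_definitions(self, cause_groups):
        lab = classify_visits(pd.DataFrame({
            "principal_dx": ["T67.0", "R50.9", "J06.9", "K52.9"],
            "secondary_dx": [[], ["E86.0"], [], []]}), cause_groups)
        shares = heat_related_shares(lab, cause_groups)
        assert shares["any_mention_pct"] == pytest.approx(50.0)
        assert shares["principal_only_pct"] == pytest.approx(25.0)

    def test_nonoverlap_groups_sum_below_allcause(self, tiny_study,
                                                  cause_groups):
        _, labeled, _ = tiny_study
        non_overlap = [g.name for g in cause_groups
                       if not g.overlap and g.name not in
                       ("all_cause", "heat_related")]
        present = [n for n in non_overlap if n in labeled.columns]
        assert labeled[present].sum().sum() <= labeled["all_cause"].sum()


class TestStrata:
    @pytest.mark.parametrize("age,expected", [
        (0, "0-5"), (5, "0-5"), (6, "6-12"), (12, "6-12"), (13, "13-17"),
        (17, "13-17")])
    def test_age_bins(self, age, expected):
        assert age_group(age) == expected

    def test_assign_stratum(self):
        key = assign_stratum(5, "female", "X", {"X": "Southeast"})
        assert key == ("0-5", "female", "Southeast")
        with pytest.raises(KeyError):
            assign_stratum(5, "female", "Y", {"X": "Southeast"})
        with pytest.raises(ValueError):
            assign_stratum(5, "unknown", "X", {"X": "Southeast"})

    def test_adult_rejected_at_ingest(self, tmp_path):
        p = tmp_path / "v.csv"
        pd.DataFrame({
            "visit_id": ["a", "b"], "date": ["2016-06-01"] * 2,
            "age_years": [17, 18], "sex": ["male", "male"],
            "county_id": ["C0", "C0"], "principal_dx": ["J45", "J45"],
            "secondary_dx": ["", ""]}).to_csv(p, index=False)
        visits, n_rejected = read_visits(p)
        assert len(visits) == 1 and n_rejected == 1

    def test_vectorized_assignment(self):
        visits = pd.DataFrame({"age_years": [3, 9, 16],
                               "county_id": ["A", "B", "A"]})
        regions = pd.DataFrame({"county_id": ["A", "B"],
                                "region": ["Midwest", "Northeast"]})
        out = assign_strata(visits, regions)
        assert list(out["age_group"]) == ["0-5", "6-12", "13-17"]
        assert list(out["region"]) == ["Midwest", "Northeast", "Midwest"]
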