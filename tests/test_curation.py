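"""Bioactivity curation: parsing, activity classes, structural filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phorescreen.curation import (
    ActivityRecord,
    ActivityType,
    apply_structural_filters,
    classify_activity,
    diversity_select,
    hinge_motif_filter,
    parse_activity_table,
)


def _rec(cid, value, stype="Ki", smiles="c1ccncc1"):
    return ActivityRecord(cid, smiles, ActivityType.parse(stype), value)


class TestParseActivityTable:
    def test_well_formed_rows_parse_without_rejects(self, tmp_path):
        p = tmp_path / "a.csv"
        pd.DataFrame(
            {
                "smiles": ["c1ccncc1", "CCO", "c1ccccc1"],
                "standard_type": ["Ki", "Kd", "IC50"],
                "standard_value": [50, 6000, 10],
            }
        ).to_csv(p, index=False)
        records, rejects = parse_activity_table(p)
        assert len(records) == 3 and rejects == []
        assert records[0].standard_type is ActivityType.Ki

    def test_non_numeric_value_routed_to_rejects(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("smiles,standard_type,standard_value\n"
                     "CCO,Ki,50\nc1ccccc1,Ki,N/A\nCCN,Kd,70\n")
        records, rejects = parse_activity_table(p)
        assert len(records) == 2
        assert len(rejects) == 1 and rejects[0][1] == "non-numeric value"

    def test_bad_smiles_routed_to_rejects(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("smiles,standard_type,standard_value\nnot_a_smiles,Ki,50\n")
        records, rejects = parse_activity_table(p)
        assert records == [] and rejects[0][1] == "unparseable SMILES"

    def test_header_only_file_yields_empty_list(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("smiles,standard_type,standard_value\n")
        records, rejects = parse_activity_table(p)
        assert records == [] and rejects == []

    def test_missing_mandatory_column_is_configuration_error(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("smiles,standard_value\nCCO,50\n")
        with pytest.raises(ValueError, match="standard_type"):
            parse_activity_table(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_activity_table(tmp_path / "nope.csv")


class TestClassifyActivity:
    def test_threshold_semantics(self):
        ls = classify_activity(
            [_rec("a", 50), _rec("b", 100), _rec("c", 2000, "Kd"),
             _rec("d", 5000), _rec("e", 9000), _rec("f", 10, "IC50")]
        )
        actives = {r.compound_id for r in ls.actives}
        inactives = {r.compound_id for r in ls.inactives}
        reasons = {r.compound_id: why for r, why in ls.excluded}
        assert actives == {"a", "b"}          # <= 100 nM, boundary inclusive
        assert inactives == {"d", "e"}        # >= 5000 nM (KNIME-style bound)
        assert reasons["c"] == "intermediate activity"
        assert reasons["f"] == "unsupported type"

    def test_exclusive_inactive_bound_flag(self):
        ls = classify_activity([_rec("a", 5000), _rec("b", 50)],
                               inactive_exclusive=True)
        assert {r.compound_id for r in ls.inactives} == set()
        assert dict((r.compound_id, w) for r, w in ls.excluded)["a"] == "intermediate activity"

    def test_duplicate_compound_keeps_most_potent(self):
        ls = classify_activity([_rec("a", 800), _rec("a", 20), _rec("a", 90)])
        assert len(ls.actives) == 1 and ls.actives[0].standard_value == 20
        assert all("duplicate" in why for _, why in ls.excluded)

    def test_negative_value_rejected_at_record_construction(self):
        with pytest.raises(ValueError, match="negative"):
            _rec("bad", -5)

    def test_inconsistent_pchembl_rejected(self):
        with pytest.raises(ValueError, match="pchembl"):
            ActivityRecord("x", "CCO", ActivityType.Ki, 100.0, pchembl_value=8.5)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        values=st.lists(st.floats(0.01, 1e6), min_size=1, max_size=40),
        types=st.lists(st.sampled_from(["Ki", "Kd", "IC50", "other"]), min_size=1, max_size=40),
    )
    def test_partition_property(self, values, types):
        n = min(len(values), len(types))
        records = [_rec(f"c{i}", values[i], types[i]) for i in range(n)]
        ls = classify_activity(records)
        assert len(ls.actives) + len(ls.inactives) + len(ls.excluded) == n

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.01, 1e6), min_size=1, max_size=30),
           st.floats(1, 99), st.floats(1, 99))
    def test_threshold_monotone(self, values, t_lo, t_hi):
        lo, hi = sorted((t_lo, t_hi))
        records = [_rec(f"c{i}", v) for i, v in enumerate(values)]
        small = {r.compound_id for r in classify_activity(records, active_nM=lo).actives}
        big = {r.compound_id for r in classify_activity(records, active_nM=hi).actives}
        assert small <= big


class TestStructuralFilters:
    def test_salt_stripped_to_parent(self):
        kept, removed = apply_structural_filters([("asa", "CC(=O)Oc1ccccc1C(=O)[O-].[Na+]")])
        assert len(kept) == 1 and removed == []
        assert "Na" not in kept[0].smiles and "." not in kept[0].smiles

    def test_mw_bound_is_inclusive(self):
        # decanoyl decaglycine-ish heavy molecule above / below the cutoff
        heavy = "C" * 40  # MW 562.1
        light = "CCO"
        kept, removed = apply_structural_filters([("h", heavy), ("l", light)], max_mw=550)
        assert [c.compound_id for c in kept] == ["l"]
        assert removed[0][1].startswith("MW >=")

    def test_duplicate_spellings_collapse(self):
        kept, removed = apply_structural_filters([("a", "OCC"), ("b", "CCO")])
        assert len(kept) == 1 and removed[0][1] == "duplicate"

    def test_unspecified_stereocenter_removed(self):
        kept, removed = apply_structural_filters(
            [("chiral", "CC(N)C(=O)O"), ("spec", "C[C@H](N)C(=O)O")]
        )
        assert [c.compound_id for c in kept] == ["spec"]
        assert removed[0][1] == "unspecified stereocenters"

    def test_idempotent(self):
        inputs = [("a", "CC(=O)Oc1ccccc1C(=O)O"), ("b", "c1ccncc1"), ("c", "CCO")]
        once, _ = apply_structural_filters(inputs)
        twice, removed = apply_structural_filters(once)
        assert [c.smiles for c in twice] == [c.smiles for c in once]
        assert removed == []


class TestHingeMotifFilter:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("c1ccncc1", True),                # pyridine
            ("Cc1ccncc1CC(=O)N", True),        # substituted pyridine
            ("c1cc[nH]n1", True),              # pyrazole (5-membered)
            ("NC1CCCCC1", False),              # cyclohexylamine, no aromatic ring
            ("c1ccc2ccccc2c1", False),         # naphthalene, nitrogen required
            ("c1ccc2ncccc2c1", True),          # quinoline, 10-atom fused aromatic + N
            ("c1ccccc1", False),               # benzene
            ("C1CCNCC1", False),               # piperidine, not aromatic
        ],
    )
    def test_motif_detection(self, smiles, expected):
        assert hinge_motif_filter(smiles) is expected


class TestDiversitySelect:
    def _compounds(self, smiles):
        kept, _ = apply_structural_filters([(f"c{i}", s) for i, s in enumerate(smiles)])
        return kept

    def test_identical_molecules_share_one_cluster(self):
        comps = self._compounds(["CCO", "OCC"])
        # duplicates collapse in filtering; re-add the same molecule twice
        comps = comps * 2
        reps, labels = diversity_select(comps)
        assert len(set(labels)) == 1 and len(reps) == 1

    def test_dissimilar_molecules_split(self):
        comps = self._compounds(["CCCCCCCC", "c1ccc2ncccc2c1"])
        reps, labels = diversity_select(comps, distance_threshold=0.5)
        assert len(reps) == 2

    def test_threshold_one_collapses_everything(self):
        comps = self._compounds(["CCO", "c1ccncc1", "CCCCC", "c1ccc2ncccc2c1"])
        reps, labels = diversity_select(comps, distance_threshold=1.0)
        assert len(reps) == 1

    def test_threshold_zero_one_rep_per_unique_structure(self):
        comps = self._compounds(["CCO", "c1ccncc1", "CCCCC"])
        reps, labels = diversity_select(comps, distance_threshold=0.0)
        assert len(reps) == len(comps)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            diversity_select([])
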