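"""Specimen ingestion, completeness filtering, size scaling and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffm.io import load_measurements, write_records_csv
from ffm.schema import DEFAULT_SCHEMA, TraitDef, TraitSchema
from ffm.trait_data import (
    SpecimenRecord,
    filter_complete,
    scale_traits,
    summarize_species,
)


def make_record(sid="f1", species="Gobio gobio", sl=100.0, **overrides):
    traits = {a: 1.0 for a in DEFAULT_SCHEMA.abbreviations}
    for b in DEFAULT_SCHEMA.binary_traits():
        traits[b] = 1.0
    traits.update(overrides)
    return SpecimenRecord(sid, species, "native", sl, traits)


class TestSchema:
    def test_default_has_22_unique_traits(self):
        assert len(DEFAULT_SCHEMA) == 22
        assert len(set(DEFAULT_SCHEMA.abbreviations)) == 22

    def test_kind_fixes_scaling(self):
        assert DEFAULT_SCHEMA["BD"].scaling == "SL"
        assert DEFAULT_SCHEMA["OpAr"].scaling == "SL2"
        assert DEFAULT_SCHEMA["OGAx"].scaling == "none"
        with pytest.raises(ValueError, match="requires scaling"):
            TraitDef("x", "X", "metric-length", scaling="none")

    def test_duplicate_abbreviation_rejected(self):
        t = TraitDef("a", "A", "ratio")
        with pytest.raises(ValueError, match="duplicate"):
            TraitSchema(traits=(t, t))


class TestLoadMeasurements:
    def test_roundtrip_community(self, community, tmp_path):
        path = tmp_path / "m.csv"
        write_records_csv(community, DEFAULT_SCHEMA, path)
        records = load_measurements(path)
        assert len(records) == 85
        assert {r.species for r in records} == {r.species for r in community}
        first = records[0]
        orig = community[0]
        assert first.standard_length == pytest.approx(orig.standard_length)
        assert first.raw_traits["BD"] == pytest.approx(orig.raw_traits["BD"])

    def test_blank_sl_row_excluded(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("species,status,SL,BD\nA,native,100,25\nB,native,,30\n")
        records = load_measurements(path)
        assert [r.species for r in records] == ["A"]

    def test_missing_required_column_is_hard_error(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("species,BD\nA,25\n")
        with pytest.raises(ValueError, match="SL"):
            load_measurements(path)
        path.write_text("SL,BD\n100,25\n")
        with pytest.raises(ValueError, match="species"):
            load_measurements(path)

    def test_unknown_column_ignored_with_warning(self, tmp_path, caplog):
        path = tmp_path / "m.csv"
        path.write_text("species,SL,BD,weight\nA,100,25,3.2\n")
        with caplog.at_level("WARNING"):
            records = load_measurements(path)
        assert "weight" not in records[0].raw_traits
        assert any("weight" in m for m in caplog.messages)

    def test_empty_table_gives_empty_list(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("species,SL,BD\n")
        assert load_measurements(path) == []

    def test_headers_match_case_insensitively_with_aliases(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("SPECIES,sl,bd,BodyDepthExtra\nA,100,25,7\n")
        records = load_measurements(path, aliases={"BodyDepthExtra": "CPD"})
        assert records[0].raw_traits == {"BD": 25.0, "CPD": 7.0}

    def test_xlsx_input(self, tmp_path):
        path = tmp_path / "m.xlsx"
        pd.DataFrame({"species": ["A"], "SL": [100.0], "BD": [25.0]}).to_excel(
            path, index=False
        )
        records = load_measurements(path)
        assert records[0].raw_traits["BD"] == 25.0


class TestFilterComplete:
    def test_removes_records_missing_any_trait(self):
        complete = [make_record(sid=f"c{i}") for i in range(9)]
        broken = make_record(sid="b1")
        del broken.raw_traits["GuL"]
        assert filter_complete(complete + [broken]) == complete

    def test_idempotent_and_identity_on_complete(self, community):
        once = filter_complete(community)
        assert once == community  # generator emits complete records
        assert filter_complete(once) == once

    def test_all_incomplete_yields_empty(self, caplog):
        rec = make_record()
        del rec.raw_traits["BD"]
        with caplog.at_level("WARNING"):
            assert filter_complete([rec]) == []


class TestScaleTraits:
    def test_scaling_rules(self):
        rec = make_record(sl=100.0, BD=25.0, OpAr=50.0, Ba=1.0, OGAx=40.0)
        m = scale_traits([rec])
        assert m.at["f1", "BD"] == pytest.approx(0.25)  # length / SL
        assert m.at["f1", "OpAr"] == pytest.approx(0.005)  # area / SL^2
        assert m.at["f1", "Ba"] == 1.0  # binary untouched
        assert m.at["f1", "OGAx"] == 40.0  # angle untouched
        assert m.attrs["scaled"] is True
        assert list(m.columns) == DEFAULT_SCHEMA.abbreviations

    def test_nonpositive_sl_names_specimen(self):
        with pytest.raises(ValueError, match="f1"):
            scale_traits([make_record(sl=0.0)])

    @settings(derandomize=True, max_examples=25)
    @given(c=st.floats(min_value=0.1, max_value=10.0))
    def test_isometry_removal(self, c):
        """Scaling is homogeneous of degree -1 in lengths and -2 in areas:
        inflating a specimen isometrically by c leaves the scaled matrix
        unchanged."""
        base = make_record(sl=80.0, BD=20.0, OpAr=30.0)
        inflated = SpecimenRecord(
            "f1", base.species, base.status, base.standard_length * c,
            {
                a: (
                    v * c if DEFAULT_SCHEMA[a].scaling == "SL"
                    else v * c**2 if DEFAULT_SCHEMA[a].scaling == "SL2"
                    else v
                )
                for a, v in base.raw_traits.items()
            },
        )
        pd.testing.assert_frame_equal(scale_traits([base]), scale_traits([inflated]))


class TestSummarizeSpecies:
    def test_two_specimen_sample_sd(self):
        recs = [make_record(sid="a", sl=40.0), make_record(sid="b", sl=60.0)]
        s = summarize_species(recs)
        row = s.iloc[0]
        assert row["n"] == 2
        assert row["sl_mean"] == 50.0
        assert row["sl_sd"] == pytest.approx(np.sqrt(200.0))  # 14.142, ddof=1

    def test_single_specimen_sd_policy(self):
        recs = [make_record(sl=50.0)]
        assert summarize_species(recs).iloc[0]["sl_sd"] == 0.0
        assert np.isnan(summarize_species(recs, single_sd=None).iloc[0]["sl_sd"])

    def test_counts_sum_to_total(self, community):
        s = summarize_species(community)
        assert s["n"].sum() == len(community)
        assert (s["sl_min"] <= s["sl_mean"]).all()
        assert (s["sl_mean"] <= s["sl_max"]).all()

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize_species([])
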