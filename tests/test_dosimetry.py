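"""Reverse-dosimetry intake estimation, stratification, and ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pahrisk import (
    BiomarkerRecord,
    PAHKinetics,
    PopulationConstants,
    Stratum,
    estimate_intake,
    estimate_population,
    rank_strata,
)
from pahrisk.dosimetry import load_biomarkers, load_kinetics
from pahrisk.errors import SchemaError, ValidationError

UNIT_KINETICS = PAHKinetics("parent", "met", 100.0, 100.0, 0.5)


class TestEstimateIntake:
    def test_worked_example(self):
        # 10 ug/L * 1.5 L/day / (0.5 * 75 kg) with unit MW ratio = 0.4 ug/kg-day
        record = BiomarkerRecord("met", 10.0)
        constants = PopulationConstants(daily_urine_output=1.5, body_weight=75.0)
        assert estimate_intake(record, UNIT_KINETICS, constants) == pytest.approx(0.4)

    def test_zero_concentration_gives_zero_intake(self):
        record = BiomarkerRecord("met", 0.0)
        assert estimate_intake(record, UNIT_KINETICS, PopulationConstants()) == 0.0

    def test_metabolite_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="met"):
            estimate_intake(BiomarkerRecord("other", 1.0), UNIT_KINETICS, PopulationConstants())

    def test_excretion_fraction_bounds_enforced(self):
        with pytest.raises(ValidationError):
            PAHKinetics("p", "m", 100.0, 100.0, 0.0)
        with pytest.raises(ValidationError):
            PAHKinetics("p", "m", 100.0, 100.0, 1.5)

    @given(factor=st.floats(0.1, 10))
    def test_linearity_and_inverse_linearity(self, factor):
        record = BiomarkerRecord("met", 10.0)
        constants = PopulationConstants(daily_urine_output=1.5, body_weight=75.0)
        base = estimate_intake(record, UNIT_KINETICS, constants)
        scaled_conc = BiomarkerRecord("met", 10.0 * factor)
        assert estimate_intake(scaled_conc, UNIT_KINETICS, constants) == pytest.approx(base * factor)
        heavier = PopulationConstants(daily_urine_output=1.5, body_weight=75.0 * factor)
        assert estimate_intake(record, UNIT_KINETICS, heavier) == pytest.approx(base / factor)
        if 0 < 0.5 * factor <= 1:
            k = PAHKinetics("parent", "met", 100.0, 100.0, 0.5 * factor)
            assert estimate_intake(record, k, constants) == pytest.approx(base / factor)


def _records_for(kinetics, concentrations):
    """One record per (metabolite, smoking level) from a nested dict."""
    out = []
    for met, by_level in concentrations.items():
        for level, conc in by_level.items():
            out.append(BiomarkerRecord(met, conc, Stratum(smoking_status=level)))
    return out


class TestPopulationTable:
    def test_cardinality_four_parents_three_strata(self, kinetics, constants):
        concs = {m: {"smoker": 3.0, "secondhand": 1.5, "nonsmoker": 1.0} for m in kinetics}
        table = estimate_population(_records_for(kinetics, concs), kinetics, constants)
        assert len(table) == 12
        assert set(table["parent"]) == {"naphthalene", "fluorene", "phenanthrene", "pyrene"}

    def test_identical_concentrations_give_identical_intakes(self, kinetics, constants):
        met = next(iter(kinetics))
        records = [
            BiomarkerRecord(met, 2.0, Stratum(gender="male")),
            BiomarkerRecord(met, 2.0, Stratum(gender="female")),
        ]
        table = estimate_population(records, kinetics, constants)
        assert table["intake_ug_kg_day"].nunique() == 1

    def test_missing_kinetics_names_the_metabolite(self, kinetics, constants):
        records = [BiomarkerRecord("unknown-metab", 1.0)]
        with pytest.raises(ValidationError, match="unknown-metab"):
            estimate_population(records, kinetics, constants)

    def test_replicates_combined_by_geometric_mean(self, constants):
        k = {"met": UNIT_KINETICS}
        records = [BiomarkerRecord("met", 1.0), BiomarkerRecord("met", 4.0)]
        table = estimate_population(records, k, constants)
        single = estimate_population([BiomarkerRecord("met", 2.0)], k, constants)
        assert table["intake_ug_kg_day"].iloc[0] == pytest.approx(
            single["intake_ug_kg_day"].iloc[0]
        )


class TestRanking:
    def test_smoker_dominated_table_ranks_smoker_first(self, kinetics, constants):
        concs = {m: {"smoker": 5.0, "secondhand": 2.0, "nonsmoker": 1.0} for m in kinetics}
        table = estimate_population(_records_for(kinetics, concs), kinetics, constants)
        ranked = rank_strata(table, "smoking_status")
        assert [name for name, _ in ranked] == ["smoker", "secondhand", "nonsmoker"]

    def test_all_equal_table_breaks_ties_alphabetically(self, kinetics, constants):
        concs = {m: {"smoker": 1.0, "secondhand": 1.0, "nonsmoker": 1.0} for m in kinetics}
        table = estimate_population(_records_for(kinetics, concs), kinetics, constants)
        ranked = rank_strata(table, "smoking_status")
        assert [name for name, _ in ranked] == ["nonsmoker", "secondhand", "smoker"]

    def test_ranking_invariant_to_row_order_and_global_scale(self, kinetics, constants):
        concs = {m: {"smoker": 4.0, "secondhand": 2.0, "nonsmoker": 1.0} for m in kinetics}
        records = _records_for(kinetics, concs)
        t1 = estimate_population(records, kinetics, constants)
        t2 = estimate_population(records[::-1], kinetics, constants)
        scaled = [
            BiomarkerRecord(r.metabolite_name, r.concentration * 7.0, r.stratum)
            for r in records
        ]
        t3 = estimate_population(scaled, kinetics, constants)
        order = lambda t: [n for n, _ in rank_strata(t, "smoking_status")]
        assert order(t1) == order(t2) == order(t3)

    def test_unknown_axis_rejected(self, kinetics, constants):
        concs = {next(iter(kinetics)): {"smoker": 1.0}}
        table = estimate_population(_records_for(kinetics, concs), kinetics, constants)
        with pytest.raises(ValidationError, match="axis"):
            rank_strata(table, "age")


class TestIO:
    def test_csv_round_trip(self, tmp_path, kinetics, constants):
        bio = tmp_path / "bio.csv"
        bio.write_text(
            "metabolite,concentration_ug_L,gender,race_ethnicity,smoking_status\n"
            "1-hydroxypyrene,0.5,male,all,all\n"
            "1-hydroxypyrene,0.3,female,all,all\n"
        )
        records = load_biomarkers(bio)
        assert len(records) == 2
        table = estimate_population(records, kinetics, constants)
        assert (table["parent"] == "pyrene").all()

    def test_kinetics_csv(self, tmp_path):
        kin = tmp_path / "kin.csv"
        kin.write_text(
            "parent,metabolite,mw_parent,mw_metabolite,excretion_fraction\n"
            "pyrene,1-hydroxypyrene,202.25,218.25,0.2\n"
        )
        loaded = load_kinetics(kin)
        assert loaded["1-hydroxypyrene"].parent_name == "pyrene"

    def test_missing_columns_raise_schema_error(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("metabolite,concentration\nx,1\n")
        with pytest.raises(SchemaError):
            load_biomarkers(bad)

    def test_unknown_stratum_vocabulary_rejected(self):
        with pytest.raises(ValidationError, match="smoking_status"):
            Stratum(smoking_status="vaper")
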