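import math

import pytest
from hypothesis import given, settings, strategies as st

from savanna_agb.exceptions import FormatError, UnclassifiableError, ValidationError
from savanna_agb.inventory import (
    DamageAssessment,
    GrowthClass,
    Plot,
    StemMeasure,
    WoodyIndividual,
    classify_growth_class,
    read_inventory,
    validate_individual,
    write_results,
)

from conftest import make_adult, make_subadult


class TestClassification:
    @pytest.mark.parametrize("ind, expected", [
        # adult-size criterion: a living stem > 15 cm basal circumference
        (make_adult(basal=20.0, loss={"fire": 5}), GrowthClass.AA),
        # heavy crown loss turns an adult into an AG1 gulliver
        (make_adult(basal=20.0, loss={"elephant": 45}), GrowthClass.AG1),
        # dead + lightly damaged living stems
        (make_adult(basal=40.0, loss={"fire": 10},
                    dead=[(30.0, ["fire"])]), GrowthClass.AG2a),
        # dead + heavily damaged living stems
        (make_adult(basal=40.0, loss={"fire": 50},
                    dead=[(30.0, ["fire"])]), GrowthClass.AG2b),
        # topkilled main stem, shrub-like regrowth measured by crown proxies
        (make_adult(height=150, cd=1.2,
                    dead=[(40.0, ["elephant"])]), GrowthClass.AG3),
        (make_subadult(height=80), GrowthClass.JU),
        (make_subadult(height=300), GrowthClass.SA),
        (make_subadult(height=80, loss={"fire": 60}), GrowthClass.GJ),
        (make_subadult(height=300, loss={"fire": 60}), GrowthClass.GS),
    ])
    def test_dispatch(self, ind, expected):
        assert classify_growth_class(ind) is expected

    def test_adult_boundary_is_strict(self):
        """A stem of exactly 15 cm basal circumference is not adult-sized."""
        at = make_adult(basal=15.0, height=120.0, cd=0.5)
        above = make_adult(basal=15.0 + 1e-9, height=120.0, cd=0.5)
        assert classify_growth_class(at) is GrowthClass.JU
        assert classify_growth_class(above) is GrowthClass.AA

    def test_gulliver_boundary_inclusive(self):
        assert classify_growth_class(
            make_adult(basal=20.0, loss={"fire": 30})) is GrowthClass.AG1
        assert classify_growth_class(
            make_adult(basal=20.0, loss={"fire": 29.999})) is GrowthClass.AA

    def test_missing_height_raises(self):
        ind = make_adult(basal=20.0)
        ind.height_cm = 0
        with pytest.raises(ValidationError):
            classify_growth_class(ind)

    def test_unclassifiable_lists_missing_fields(self):
        """Dead adult stem with no living-part proxies cannot be classified."""
        ind = make_adult(dead=[(40.0, ["fire"])], cd=None)
        with pytest.raises(UnclassifiableError) as err:
            classify_growth_class(ind)
        assert "crown_diameter_1_m" in err.value.missing

    @settings(max_examples=100, deadline=None)
    @given(
        heavy=st.floats(30.0, 99.0),
        light=st.floats(0.0, 29.999),
        tier=st.sampled_from(["JU", "SA", "AA"]),
    )
    def test_loss_moves_class_within_size_tier(self, heavy, light, tier):
        """Raising losses past the threshold changes only the damage status,
        never the size tier."""
        if tier == "AA":
            lo = make_adult(basal=25.0, loss={"fire": light})
            hi = make_adult(basal=25.0, loss={"fire": heavy})
            assert classify_growth_class(lo) is GrowthClass.AA
            assert classify_growth_class(hi) is GrowthClass.AG1
        else:
            h = 80.0 if tier == "JU" else 300.0
            lo = make_subadult(height=h, loss={"fire": light})
            hi = make_subadult(height=h, loss={"fire": heavy})
            assert classify_growth_class(lo).value == tier
            assert classify_growth_class(hi).value == ("G" + tier[0] if tier == "JU" else "GS")


class TestValidation:
    def test_intact_record_is_clean(self):
        assert validate_individual(make_adult(basal=20.0, circ130=18.0)) == []

    def test_loss_sum_cap(self):
        ind = make_subadult(loss={"elephant": 60, "fire": 50})
        violations = validate_individual(ind)
        assert any("sum of losses 110" in v for v in violations)

    def test_alt_pair_rule(self):
        ind = make_adult(basal=20.0)
        ind.stems[0].alt_circ_cm = 12.0  # without alt_height
        assert sum("together" in v for v in validate_individual(ind)) == 1

    def test_dead_stem_needs_topkill_agent(self):
        ind = make_adult(height=150, cd=1.0, dead=[(40.0, ["fire"])])
        ind.stems[0].topkill_agents = ()
        assert any("topkill" in v for v in validate_individual(ind))

    def test_edge_fraction_range(self):
        ind = make_subadult()
        ind.edge_fraction = 1.5
        assert any("edge_fraction" in v for v in validate_individual(ind))


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path, noisy_study):
        individuals = noisy_study.individuals[:200]
        plots = noisy_study.plots
        write_results(individuals, plots, tmp_path)
        back_ind, back_plots = read_inventory(tmp_path)
        assert len(back_ind) == len(individuals)
        assert len(back_plots) == len(plots)
        for a, b in zip(individuals, back_ind):
            assert a.individual_id == b.individual_id
            assert a.height_cm == b.height_cm
            assert a.damage.loss_percent_by_agent == b.damage.loss_percent_by_agent
            assert len(a.stems) == len(b.stems)
            for sa_, sb in zip(a.stems, b.stems):
                assert sa_.basal_circ_cm == sb.basal_circ_cm
                assert sa_.is_dead == sb.is_dead
                assert sa_.topkill_agents == sb.topkill_agents
        for pa, pb in zip(plots, back_plots):
            assert pa.realized_area_by_class == pb.realized_area_by_class

    def test_empty_tables(self, tmp_path):
        write_results([], [], tmp_path)
        individuals, plots = read_inventory(tmp_path)
        assert individuals == [] and plots == []

    def test_missing_columns_reported(self, tmp_path):
        write_results([], [], tmp_path)
        (tmp_path / "individuals.csv").write_text("individual_id,plot_id\n")
        with pytest.raises(FormatError, match="height_cm"):
            read_inventory(tmp_path)

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(FormatError):
            read_inventory(tmp_path, dialect="tsv")


class TestXlsxAdapter:
    def test_reads_multisheet_workbook(self, tmp_path):
        """Synthetic field workbook in the deposited-dataset sheet layout."""
        import pandas as pd
        from savanna_agb.inventory import individuals_to_frames, plots_to_frame

        individuals = [make_subadult(individual_id=f"S{i}") for i in range(3)]
        plot = Plot(plot_id="P001", vegetation="savanna", density_level="low",
                    realized_area_by_class={"JU": 100.0})
        ind_df, stem_df = individuals_to_frames(individuals)
        path = tmp_path / "field.xlsx"
        with pd.ExcelWriter(path) as xl:
            pd.DataFrame({"info": ["synthetic workbook"]}).to_excel(
                xl, sheet_name="basic info", index=False)
            ind_df.to_excel(xl, sheet_name="raw dendrometrics", index=False)
            stem_df.to_excel(xl, sheet_name="stems", index=False)
            plots_to_frame([plot]).to_excel(xl, sheet_name="coordinates", index=False)
        back_ind, back_plots = read_inventory(path, dialect="mendeley_xlsx")
        assert [i.individual_id for i in back_ind] == ["S0", "S1", "S2"]
        assert back_plots[0].realized_area_by_class["JU"] == 100.0

    def test_missing_sheet_reported(self, tmp_path):
        import pandas as pd
        path = tmp_path / "bad.xlsx"
        pd.DataFrame({"x": [1]}).to_excel(path, sheet_name="unrelated", index=False)
        with pytest.raises(FormatError, match="sheet"):
            read_inventory(path, dialect="mendeley_xlsx")


def test_unknown_agent_mapped_to_other():
    with pytest.warns(UserWarning, match="mapped to 'other'"):
        dmg = DamageAssessment(loss_percent_by_agent={"meteor strike": 10})
    assert dmg.loss_percent_by_agent == {"other": 10.0}


def test_plot_area_invariant():
    plot = Plot(plot_id="P1", realized_area_by_class={"JU": 2000.0},
                plot_area_m2=1000.0)
    assert any("realized area" in v for v in plot.validate())
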