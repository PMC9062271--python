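import math

import pytest
from hypothesis import given, settings, strategies as st

from savanna_agb.calibration import CalibrationModels
from savanna_agb.estimation import (
    BiomassEstimator,
    assign_topkill_loss,
    dead_stem_agb,
    estimate_individual,
    partition_canopy_losses,
    results_to_frame,
    reverse_damage,
)
from savanna_agb.exceptions import (
    ConfigurationError,
    EstimationError,
    SwdLookupError,
    ValidationError,
)
from savanna_agb.inventory import (
    DamageAssessment,
    GrowthClass,
    StemMeasure,
    classify_growth_class,
)
from savanna_agb.wood_density import SpeciesDensityTable

from conftest import make_adult, make_subadult, circ_of_dbh

SWD_TABLE = SpeciesDensityTable(values={
    "Burkea africana": (0.6, 3), "Ochna pulchra": (0.58, 2),
})

# frozen chained-oracle values (independent direct evaluation)
AA_PRE = 353.2744833716337          # stem model at SWD .6, DBH 30, h 12 m
AG3_STANDING = 149.38667209807525   # canopy model at CD 2 m, h 300 cm
DEAD_LOSS_100 = 187.22925372411692  # dead-stem chain from basal circ 100 cm


def classified(ind):
    ind.growth_class = classify_growth_class(ind)
    return ind


class TestWorkedFlows:
    def test_healthy_adult(self, paper_models):
        ind = classified(make_adult(circ130=circ_of_dbh(30), basal=125.0, height=1200.0))
        r = estimate_individual(ind, SWD_TABLE, paper_models)
        assert r.growth_class is GrowthClass.AA and r.model_used == "stem"
        assert r.agb_standing == pytest.approx(AA_PRE, rel=1e-12)
        assert r.agb_ex == pytest.approx(AA_PRE, rel=1e-12)
        assert r.loss_by_agent == {}

    def test_adult_with_crown_loss(self, paper_models):
        """Stem-model output is pre-disturbance; losses are deducted."""
        ind = classified(make_adult(circ130=circ_of_dbh(30), basal=125.0,
                                    height=1200.0, loss={"elephant": 20}))
        r = estimate_individual(ind, SWD_TABLE, paper_models)
        assert r.agb_standing == pytest.approx(0.8 * AA_PRE, rel=1e-12)
        assert r.loss_by_agent["elephant"] == pytest.approx(0.2 * AA_PRE, rel=1e-12)
        assert r.agb_ex == pytest.approx(AA_PRE, rel=1e-12)

    def test_ag1_height_correction(self, paper_models):
        """A shortened heavy-loss adult is restored to its allometric height."""
        dbh = 30.0
        h_obs = 300.0  # far below the allometric expectation
        ind = classified(make_adult(circ130=circ_of_dbh(dbh), basal=125.0,
                                    height=h_obs, loss={"elephant": 50}))
        assert ind.growth_class is GrowthClass.AG1
        h_est = math.exp(paper_models.a + paper_models.b * math.log(dbh))
        pre = 0.0673 * (0.6 * dbh ** 2 * h_est / 100.0) ** 0.976
        r = estimate_individual(ind, SWD_TABLE, paper_models)
        assert r.agb_ex == pytest.approx(pre, rel=1e-12)
        assert r.agb_standing == pytest.approx(0.5 * pre, rel=1e-12)

    def test_ag2a_no_height_correction(self, paper_models):
        """Living stems with intact crowns keep their observed height."""
        ind = classified(make_adult(
            circ130=circ_of_dbh(30), basal=125.0, height=300.0,
            loss={"fire": 10}, dead=[(100.0, ["fire"])],
        ))
        assert ind.growth_class is GrowthClass.AG2a
        pre_live = 0.0673 * (0.6 * 900 * 3.0) ** 0.976  # observed 3 m height
        r = estimate_individual(ind, SWD_TABLE, paper_models)
        assert r.agb_standing == pytest.approx(0.9 * pre_live, rel=1e-12)
        assert r.dead_stem_loss == pytest.approx(DEAD_LOSS_100, rel=1e-12)
        assert r.loss_by_agent["fire"] == pytest.approx(
            0.1 * pre_live + DEAD_LOSS_100, rel=1e-12)
        assert r.agb_ex == pytest.approx(pre_live + DEAD_LOSS_100, rel=1e-12)

    def test_ag2b_height_corrected_living_stems(self, paper_models):
        ind = classified(make_adult(
            circ130=circ_of_dbh(30), basal=125.0, height=300.0,
            loss={"elephant": 60}, dead=[(100.0, ["elephant"])],
        ))
        assert ind.growth_class is GrowthClass.AG2b
        h_est = math.exp(paper_models.a + paper_models.b * math.log(30.0))
        pre_live = 0.0673 * (0.6 * 900 * h_est / 100.0) ** 0.976
        r = estimate_individual(ind, SWD_TABLE, paper_models)
        assert r.agb_ex == pytest.approx(pre_live + DEAD_LOSS_100, rel=1e-12)
        assert r.agb_standing == pytest.approx(0.4 * pre_live, rel=1e-12)

    def test_ag3_combined_models(self, paper_models):
        """Living regrowth by the canopy model; topkill loss from the dead stem."""
        ind = classified(make_adult(height=300.0, cd=2.0,
                                    dead=[(100.0, ["fire"])]))
        assert ind.growth_class is GrowthClass.AG3
        r = estimate_individual(ind, SWD_TABLE, paper_models)
        assert r.model_used == "combined"
        assert r.agb_standing == pytest.approx(AG3_STANDING, rel=1e-12)
        assert r.loss_by_agent == {"fire": pytest.approx(DEAD_LOSS_100, rel=1e-12)}
        assert r.agb_ex == pytest.approx(AG3_STANDING + DEAD_LOSS_100, rel=1e-12)

    def test_subadult_canopy_is_post_disturbance(self, paper_models):
        """Canopy-model output is standing AGB; the pre value is recovered
        by reverse damage assessment."""
        ind = classified(make_subadult(height=120.0, cd=0.8, loss={"fire": 25}))
        post = math.exp(-0.370 + 1.903 * math.log(0.8) + 0.652 * math.log(120.0)) * 1.403
        r = estimate_individual(ind, SWD_TABLE, paper_models)
        assert r.agb_standing == pytest.approx(post, rel=1e-12)
        assert r.agb_ex == pytest.approx(post / 0.75, rel=1e-12)
        assert r.loss_by_agent["fire"] == pytest.approx(post / 0.75 * 0.25, rel=1e-12)

    def test_multi_stem_sums_with_shared_height(self, paper_models):
        ind = make_adult(circ130=circ_of_dbh(30), basal=125.0, height=1200.0)
        ind.stems.append(StemMeasure(basal_circ_cm=circ_of_dbh(20)))
        classified(ind)
        dbh2 = paper_models.s * circ_of_dbh(20) / math.pi
        expected = AA_PRE + 0.0673 * (0.6 * dbh2 ** 2 * 12.0) ** 0.976
        r = estimate_individual(ind, SWD_TABLE, paper_models)
        assert r.agb_standing == pytest.approx(expected, rel=1e-12)


class TestDeadStem:
    def test_chained_oracle_value(self, paper_models):
        stem = StemMeasure(basal_circ_cm=100.0, is_dead=True, topkill_agents=("fire",))
        assert dead_stem_agb(stem, 0.6, paper_models) == pytest.approx(
            DEAD_LOSS_100, rel=1e-12)

    def test_alternative_at_base_reduces_to_basal(self, paper_models):
        """A reading at hx = 0 is exactly a basal reading."""
        basal = StemMeasure(basal_circ_cm=80.0, is_dead=True, topkill_agents=("fire",))
        alt = StemMeasure(alt_circ_cm=80.0, alt_height_cm=0.0, is_dead=True,
                          topkill_agents=("fire",))
        assert dead_stem_agb(alt, 0.6, paper_models) == pytest.approx(
            dead_stem_agb(basal, 0.6, paper_models), rel=1e-12)

    def test_two_dead_stems_losses_sum(self, paper_models):
        ind = classified(make_adult(
            height=200.0, cd=1.5,
            dead=[(100.0, ["fire"]), (100.0, ["fire"])],
        ))
        r = estimate_individual(ind, SWD_TABLE, paper_models)
        assert r.dead_stem_loss == pytest.approx(2 * DEAD_LOSS_100, rel=1e-12)

    def test_dead_stem_never_in_standing(self, paper_models):
        """Removing a dead stem changes only losses, not standing AGB."""
        with_dead = classified(make_adult(
            circ130=circ_of_dbh(30), basal=125.0, height=1200.0,
            loss={"fire": 10}, dead=[(100.0, ["fire"])]))
        without = classified(make_adult(
            circ130=circ_of_dbh(30), basal=125.0, height=1200.0,
            loss={"fire": 10}))
        r1 = estimate_individual(with_dead, SWD_TABLE, paper_models)
        r2 = estimate_individual(without, SWD_TABLE, paper_models)
        assert r1.agb_standing == pytest.approx(r2.agb_standing, rel=1e-12)
        assert r1.total_loss > r2.total_loss

    def test_unusable_stem_rejected(self, paper_models):
        stem = StemMeasure(is_dead=True, topkill_agents=("fire",))
        with pytest.raises(EstimationError):
            dead_stem_agb(stem, 0.6, paper_models)


class TestPartitioning:
    def test_single_agent(self):
        losses, standing = partition_canopy_losses(
            100.0, DamageAssessment({"fire": 30}))
        assert losses == {"fire": 30.0} and standing == 70.0

    def test_topkill_floor(self):
        """99% total loss leaves a 1% living remainder."""
        losses, standing = partition_canopy_losses(
            100.0, DamageAssessment({"fire": 50, "elephant": 49}))
        assert standing == pytest.approx(1.0)

    def test_empty_damage(self):
        losses, standing = partition_canopy_losses(100.0, DamageAssessment())
        assert losses == {} and standing == 100.0

    def test_over_cap_rejected(self):
        with pytest.raises(ValidationError):
            partition_canopy_losses(100.0, DamageAssessment({"fire": 60, "elephant": 50}))

    @pytest.mark.parametrize("post, pct, pre", [
        (50.0, 50.0, 100.0),
        (77.0, 0.0, 77.0),
        (1.0, 99.0, 100.0),
    ])
    def test_reverse_damage(self, post, pct, pre):
        assert reverse_damage(post, pct) == pytest.approx(pre)

    def test_reverse_damage_range(self):
        with pytest.raises(ValidationError):
            reverse_damage(1.0, 100.0)

    @settings(max_examples=200, deadline=None)
    @given(post=st.floats(0.01, 1e4), fire=st.floats(0, 60), eleph=st.floats(0, 39))
    def test_partition_reverse_round_trip(self, post, fire, eleph):
        """Forward partition of the reverse-recovered pre returns post exactly."""
        dmg = DamageAssessment({"fire": fire, "elephant": eleph})
        pre = reverse_damage(post, dmg.total_percent)
        _, standing = partition_canopy_losses(pre, dmg)
        assert standing == pytest.approx(post, rel=1e-9)

    def test_topkill_split(self):
        assert assign_topkill_loss(100.0, ("fire",)) == {"fire": 100.0}
        assert assign_topkill_loss(100.0, ("fire", "elephant")) == {
            "fire": 50.0, "elephant": 50.0}
        assert assign_topkill_loss(0.0, ("fire",)) == {"fire": 0.0}
        with pytest.raises(ValidationError):
            assign_topkill_loss(10.0, ())
        with pytest.raises(ValidationError):
            assign_topkill_loss(10.0, ("a", "b", "c"))


class TestErrors:
    def test_missing_growth_class(self, paper_models):
        ind = make_subadult()
        with pytest.raises(EstimationError, match="growth class"):
            estimate_individual(ind, SWD_TABLE, paper_models)

    def test_canopy_class_needs_crown_diameters(self, paper_models):
        ind = make_subadult(cd=None)
        ind.growth_class = GrowthClass.SA
        with pytest.raises(EstimationError, match="crown"):
            estimate_individual(ind, SWD_TABLE, paper_models)

    def test_stem_class_needs_living_stem(self, paper_models):
        ind = make_adult(cd=1.0, height=300.0)
        ind.growth_class = GrowthClass.AA
        with pytest.raises(EstimationError, match="living stem"):
            estimate_individual(ind, SWD_TABLE, paper_models)

    def test_unresolvable_species(self, paper_models):
        ind = classified(make_adult(circ130=circ_of_dbh(30), basal=125.0,
                                    species="Adansonia digitata"))
        with pytest.raises(SwdLookupError):
            estimate_individual(ind, SWD_TABLE, paper_models)


class TestConservation:
    def test_all_simulated_records_conserve(self, noisy_study):
        """agb_ex = standing + sum of losses for every individual."""
        for r in noisy_study.truth:
            assert abs(r.agb_ex - (r.agb_standing + r.total_loss)) <= \
                1e-9 * max(r.agb_ex, 1e-300)


class TestBiomassEstimator:
    def test_sklearn_protocol(self):
        from sklearn.base import clone

        est = BiomassEstimator(default_swd=0.6)
        params = est.get_params()
        assert params["gulliver_loss_threshold"] == 30.0
        clone(est)

    def test_fit_transform_frame(self, noisy_study):
        est = BiomassEstimator()
        est.fit(noisy_study.individuals, wood_samples=noisy_study.wood_samples)
        assert est.calibration_.provenance == "local"
        df = est.transform(noisy_study.individuals[:50])
        assert list(df.columns[:4]) == [
            "individual_id", "growth_class", "agb_standing_kg", "agb_ex_kg"]
        assert len(df) == 50
        assert (df["agb_standing_kg"] >= 0).all()

    def test_paper_calibration_option(self):
        est = BiomassEstimator(calibration="paper", default_swd=0.6)
        est.fit([make_subadult()])
        assert est.calibration_.provenance == "paper-default"

    def test_auto_falls_back_with_warning(self):
        est = BiomassEstimator(default_swd=0.6)
        with pytest.warns(UserWarning, match="falling back"):
            est.fit([make_subadult()])
        assert est.calibration_.provenance == "paper-default"

    def test_unfitted_raises(self):
        with pytest.raises(ConfigurationError):
            BiomassEstimator().estimate([make_subadult()])

    def test_invalid_calibration_param(self):
        with pytest.raises(ConfigurationError):
            BiomassEstimator(calibration="nonsense").fit([make_subadult()])
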