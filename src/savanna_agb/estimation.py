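"""Per-individual AGB and AGB-loss estimation, dispatched on growth class.

The central accounting identity is conservation:

    AGB_ex = AGB_standing + sum of per-agent losses

where AGB_ex is the extrapolated pre-disturbance biomass. The two allometric
model families enter this identity from opposite ends:

* stem-based classes (AA, AG1, AG2a, AG2b): the model output is the
  *pre-disturbance* value; recorded percentage losses are deducted to get
  standing AGB;
* canopy-based classes (JU, SA, GJ, GS, and the living part of AG3): the
  model output already reflects the damaged state (*post*-disturbance);
  the pre-disturbance value is recovered by reverse damage assessment,
  agb_pre = agb_post / (1 - total_loss/100).

Dead adult-sized stems are never part of standing AGB. Their former biomass
is reconstructed through the proxy chain (alternative reading -> basal
circumference -> surrogate DBH -> reconstructed height -> stem model) and
booked as a loss under the recorded topkill agent(s) — split equally when
two joint agents were listed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import allometry
from .calibration import CalibrationModels
from .exceptions import (
    ConfigurationError,
    EstimationError,
    ValidationError,
)
from .inventory import (
    AGENTS,
    DEFAULT_ADULT_CIRC_THRESHOLD,
    DEFAULT_GULLIVER_LOSS_THRESHOLD,
    DEFAULT_JUVENILE_HEIGHT_THRESHOLD,
    MAX_TOTAL_LOSS_PERCENT,
    DamageAssessment,
    GrowthClass,
    StemMeasure,
    WoodyIndividual,
    classify_growth_class,
    validate_individual,
)
from .wood_density import SpeciesDensityTable

#: Relative tolerance for the conservation identity check.
CONSERVATION_RTOL = 1e-9


@dataclass
class IndividualBiomass:
    """AGB partitions for one woody individual, all in kg."""

    individual_id: str
    growth_class: GrowthClass
    agb_standing: float
    agb_ex: float
    loss_by_agent: dict[str, float] = field(default_factory=dict)
    dead_stem_loss: float = 0.0
    model_used: str = "stem"  # stem | canopy | combined
    swd_provenance: str | None = None

    @property
    def total_loss(self) -> float:
        return sum(self.loss_by_agent.values())

    def check_conservation(self) -> None:
        expected = self.agb_standing + self.total_loss
        scale = max(abs(self.agb_ex), abs(expected), 1e-300)
        if abs(self.agb_ex - expected) > CONSERVATION_RTOL * scale:
            raise ValidationError(
                f"{self.individual_id}: conservation violated, "
                f"agb_ex={self.agb_ex} vs standing+losses={expected}"
            )


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def partition_canopy_losses(
    agb_pre: float, damage: DamageAssessment
) -> tuple[dict[str, float], float]:
    """Split pre-disturbance AGB into per-agent losses and the standing rest.

    loss_agent = agb_pre * percent/100; standing = agb_pre - sum(losses).
    At the 99% cap (total topkill) a 1% living remainder survives.
    """
    violations = damage.validate()
    if violations:
        raise ValidationError("; ".join(violations))
    losses = {
        agent: agb_pre * pct / 100.0
        for agent, pct in damage.loss_percent_by_agent.items()
        if pct > 0
    }
    return losses, agb_pre - sum(losses.values())


def reverse_damage(agb_post: float, total_loss_percent: float) -> float:
    """Pre-disturbance AGB from a post-disturbance estimate and total loss %.

    Inverse of the forward partition: agb_pre = agb_post / (1 - p/100).
    """
    if not 0 <= total_loss_percent <= MAX_TOTAL_LOSS_PERCENT:
        raise ValidationError(
            f"total loss percent must be in [0, {MAX_TOTAL_LOSS_PERCENT:g}], "
            f"got {total_loss_percent}"
        )
    return agb_post / (1.0 - total_loss_percent / 100.0)


def assign_topkill_loss(
    dead_loss_kg: float, agents: Sequence[str]
) -> dict[str, float]:
    """Allocate a dead stem's former AGB to its topkill agent(s).

    A single agent receives everything; two joint agents split equally.
    """
    if not agents:
        raise ValidationError("a dead stem must name at least one topkill agent")
    if len(agents) > 2:
        raise ValidationError(f"at most two joint topkill agents, got {len(agents)}")
    share = dead_loss_kg / len(agents)
    out: dict[str, float] = {}
    for a in agents:
        out[a] = out.get(a, 0.0) + share
    return out


def stem_dbh(stem: StemMeasure, model: CalibrationModels) -> float:
    """Measured or surrogate DBH (cm) for a stem.

    Preference order: measured circumference at 130 cm; else surrogate from
    basal circumference; else surrogate from the alternative reading via the
    taper reconstruction.
    """
    if stem.circ130_cm is not None:
        return stem.circ130_cm / math.pi
    basal = stem.basal_circ_cm
    if basal is None and stem.alt_circ_cm is not None:
        basal = allometry.basal_from_alternative(
            stem.alt_circ_cm, stem.alt_height_cm, model
        )
    if basal is None:
        raise EstimationError(
            "stem has no usable circumference (need circ130, basal, or the "
            "alternative pair)"
        )
    return allometry.dbh_from_basal(basal, model)


def dead_stem_agb(
    stem: StemMeasure, species_swd: float, model: CalibrationModels
) -> float:
    """Former AGB (kg) of a dead adult-sized stem.

    Surrogate DBH from basal (or alternative) circumference, reconstructed
    height from that DBH, then the stem model (height converted cm -> m).
    """
    if not stem.is_dead:
        raise EstimationError("dead_stem_agb called on a living stem")
    basal = stem.basal_circ_cm
    if basal is None and stem.alt_circ_cm is not None:
        basal = allometry.basal_from_alternative(
            stem.alt_circ_cm, stem.alt_height_cm, model
        )
    if basal is None:
        raise EstimationError(
            "dead stem has no usable circumference (need basal or alternative)"
        )
    dbh = allometry.dbh_from_basal(basal, model)
    h_est_cm = allometry.height_from_dbh(dbh, model.a, model.b)
    return allometry.stem_agb(species_swd, dbh, h_est_cm / 100.0)


# ---------------------------------------------------------------------------
# Growth-class dispatch
# ---------------------------------------------------------------------------

#: Per-class workflow flags: which model family carries the living part,
#: whether living stems get the pre-disturbance height correction, and
#: whether dead-stem losses are expected for the class.
_WORKFLOW = {
    GrowthClass.JU:   ("canopy", False),
    GrowthClass.SA:   ("canopy", False),
    GrowthClass.GJ:   ("canopy", False),
    GrowthClass.GS:   ("canopy", False),
    GrowthClass.AA:   ("stem", False),
    GrowthClass.AG1:  ("stem", True),
    GrowthClass.AG2a: ("stem", False),
    GrowthClass.AG2b: ("stem", True),
    GrowthClass.AG3:  ("canopy", False),
}


def _merge(into: dict[str, float], extra: dict[str, float]) -> None:
    for k, v in extra.items():
        into[k] = into.get(k, 0.0) + v


def estimate_individual(
    ind: WoodyIndividual,
    swd_table: SpeciesDensityTable,
    model: CalibrationModels,
) -> IndividualBiomass:
    """Estimate standing AGB, pre-disturbance AGB and per-agent losses.

    The individual must already carry a growth class (see
    :func:`savanna_agb.inventory.classify_growth_class`). Multi-stem
    individuals share one height; per-stem AGB is summed.
    """
    if ind.growth_class is None:
        raise EstimationError(
            f"{ind.individual_id}: growth class not set; classify before estimating"
        )
    violations = validate_individual(ind)
    if violations:
        raise ValidationError("; ".join(violations))

    gc = ind.growth_class
    living_model, height_correction = _WORKFLOW[gc]
    swd = provenance = None

    def resolve_swd() -> float:
        nonlocal swd, provenance
        if swd is None:
            swd, provenance = swd_table.lookup(ind.species)
        return swd

    losses: dict[str, float] = {}

    if living_model == "canopy":
        cd = ind.mean_crown_diameter_m
        if cd is None:
            raise EstimationError(
                f"{ind.individual_id} ({gc.value}): canopy workflow needs both "
                "crown diameters"
            )
        agb_post = allometry.canopy_agb(cd, ind.height_cm)
        agb_pre = reverse_damage(agb_post, ind.damage.total_percent)
        canopy_losses, standing = partition_canopy_losses(agb_pre, ind.damage)
        _merge(losses, canopy_losses)
    else:
        living = [
            s for s in ind.living_stems()
            if s.circ130_cm is not None or s.basal_circ_cm is not None
            or s.alt_circ_cm is not None
        ]
        if not living:
            raise EstimationError(
                f"{ind.individual_id} ({gc.value}): stem workflow needs at least "
                "one living stem with a circumference measure"
            )
        agb_pre = 0.0
        for s in living:
            dbh = stem_dbh(s, model)
            h_cm = (
                allometry.reconstruct_height(dbh, ind.height_cm, model)
                if height_correction else ind.height_cm
            )
            agb_pre += allometry.stem_agb(resolve_swd(), dbh, h_cm / 100.0)
        canopy_losses, standing = partition_canopy_losses(agb_pre, ind.damage)
        _merge(losses, canopy_losses)

    dead_loss = 0.0
    for s in ind.dead_stems():
        loss = dead_stem_agb(s, resolve_swd(), model)
        _merge(losses, assign_topkill_loss(loss, s.topkill_agents))
        dead_loss += loss

    model_used = living_model if dead_loss == 0 else (
        "combined" if living_model == "canopy" else "stem"
    )
    result = IndividualBiomass(
        individual_id=ind.individual_id,
        growth_class=gc,
        agb_standing=standing,
        agb_ex=agb_pre + dead_loss,
        loss_by_agent=losses,
        dead_stem_loss=dead_loss,
        model_used=model_used,
        swd_provenance=provenance,
    )
    result.check_conservation()
    return result


def results_to_frame(results: Iterable[IndividualBiomass]) -> pd.DataFrame:
    """Per-individual results table with one loss column per agent."""
    rows = []
    for r in results:
        row = {
            "individual_id": r.individual_id,
            "growth_class": r.growth_class.value,
            "agb_standing_kg": r.agb_standing,
            "agb_ex_kg": r.agb_ex,
        }
        for agent in AGENTS:
            row[f"loss_{agent}_kg"] = r.loss_by_agent.get(agent, 0.0)
        row["dead_stem_loss_kg"] = r.dead_stem_loss
        row["model_used"] = r.model_used
        rows.append(row)
    cols = (
        ["individual_id", "growth_class", "agb_standing_kg", "agb_ex_kg"]
        + [f"loss_{a}_kg" for a in AGENTS]
        + ["dead_stem_loss_kg", "model_used"]
    )
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class BiomassEstimator(BaseEstimator, TransformerMixin):
    """Inventory -> per-individual AGB partitions, as a sklearn transformer.

    ``fit`` classifies the individuals, learns the species wood-density
    table from wood samples (if given) and calibrates the three proxy
    regressions from the healthy adult subset; ``transform`` runs the
    growth-class-dispatched estimation and returns the per-individual
    results table.

    Parameters
    ----------
    adult_circ_threshold : cm, stems strictly above are adult-sized.
    gulliver_loss_threshold : percent, at or above marks a gulliver.
    juvenile_height_threshold : cm, boundary between juvenile and sapling.
    calibration : "auto" fits locally and falls back to the printed
        reference coefficients when too few reference trees exist; "paper"
        always uses the printed coefficients; or pass a fitted
        :class:`CalibrationModels`.
    default_swd : optional global wood-density fallback, g cm^-3.
    """

    def __init__(
        self,
        adult_circ_threshold: float = DEFAULT_ADULT_CIRC_THRESHOLD,
        gulliver_loss_threshold: float = DEFAULT_GULLIVER_LOSS_THRESHOLD,
        juvenile_height_threshold: float = DEFAULT_JUVENILE_HEIGHT_THRESHOLD,
        calibration: str | CalibrationModels = "auto",
        default_swd: float | None = None,
    ):
        self.adult_circ_threshold = adult_circ_threshold
        self.gulliver_loss_threshold = gulliver_loss_threshold
        self.juvenile_height_threshold = juvenile_height_threshold
        self.calibration = calibration
        self.default_swd = default_swd

    def _classify_all(self, X: Sequence[WoodyIndividual]) -> list[WoodyIndividual]:
        for ind in X:
            ind.growth_class = classify_growth_class(
                ind,
                adult_circ_threshold=self.adult_circ_threshold,
                gulliver_loss_threshold=self.gulliver_loss_threshold,
                juvenile_height_threshold=self.juvenile_height_threshold,
            )
        return list(X)

    def fit(self, X: Sequence[WoodyIndividual], y=None, wood_samples=None,
            swd_table: SpeciesDensityTable | None = None):
        X = self._classify_all(X)
        if swd_table is not None:
            self.swd_table_ = swd_table
        elif wood_samples:
            from .wood_density import species_mean_table
            self.swd_table_ = species_mean_table(
                wood_samples, default_swd=self.default_swd
            )
        else:
            self.swd_table_ = SpeciesDensityTable(default_swd=self.default_swd)

        if isinstance(self.calibration, CalibrationModels):
            self.calibration_ = self.calibration
        elif self.calibration == "paper":
            self.calibration_ = CalibrationModels.paper_defaults()
        elif self.calibration == "auto":
            try:
                self.calibration_ = CalibrationModels.fit(
                    X, gulliver_loss_threshold=self.gulliver_loss_threshold
                )
            except ConfigurationError as exc:
                warnings.warn(
                    f"local calibration not possible ({exc}); falling back to "
                    "the printed reference coefficients"
                )
                self.calibration_ = CalibrationModels.paper_defaults()
        else:
            raise ConfigurationError(
                f"calibration must be 'auto', 'paper' or CalibrationModels, "
                f"got {self.calibration!r}"
            )
        self.n_individuals_ = len(X)
        return self

    def estimate(self, X: Sequence[WoodyIndividual]) -> list[IndividualBiomass]:
        if not hasattr(self, "calibration_"):
            raise ConfigurationError("BiomassEstimator is not fitted")
        X = [
            ind if ind.growth_class is not None else self._classify_all([ind])[0]
            for ind in X
        ]
        return [
            estimate_individual(ind, self.swd_table_, self.calibration_)
            for ind in X
        ]

    def transform(self, X: Sequence[WoodyIndividual]) -> pd.DataFrame:
        return results_to_frame(self.estimate(X))
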