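"""Upscaling individual AGB values to unit area, plot and stratum summaries.

Each growth class is recorded on its own nested subplot, so each individual
carries the upscaling factor of its class's realized sampling area:
factor = 1 ha / realized area (m²). Edge individuals are additionally
weighted by the fraction falling inside the plot. Plot totals are sums of
the individually upscaled partitions (kg ha^-1); stratum summaries report
means and standard deviations over replicate plots. AGB_pot — the maximum
potential stand biomass per vegetation type — is taken from mean AGB_ex in
the reference stratum of lowest elephant disturbance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .estimation import IndividualBiomass
from .exceptions import ConfigurationError, ValidationError
from .inventory import AGENTS, GrowthClass, Plot, StudyDesign, area_group

#: One hectare in m².
HECTARE_M2 = 10_000.0


def upscaling_factor(realized_area_m2: float) -> float:
    """1 ha divided by the realized sampling area of a growth class."""
    if not 0 < realized_area_m2 <= HECTARE_M2:
        raise ValidationError(
            f"realized area must be in (0, {HECTARE_M2:g}] m2, got {realized_area_m2}"
        )
    return HECTARE_M2 / realized_area_m2


@dataclass
class ScaledRecord:
    """One individual's AGB partitions on a per-hectare basis (kg ha^-1)."""

    individual_id: str
    plot_id: str
    growth_class: GrowthClass
    agb_standing: float
    agb_ex: float
    loss_by_agent: dict[str, float]
    dead_stem_loss: float


def scale_individual(
    ib: IndividualBiomass,
    plot: Plot,
    edge_fraction: float = 1.0,
) -> ScaledRecord:
    """Apply the class upscaling factor and edge correction to all partitions."""
    area = plot.realized_area(ib.growth_class)
    if area is None:
        raise ConfigurationError(
            f"plot {plot.plot_id}: no realized sampling area recorded for "
            f"class group {area_group(ib.growth_class)!r}"
        )
    if not 0 < edge_fraction <= 1:
        raise ValidationError(f"edge_fraction must be in (0, 1], got {edge_fraction}")
    w = upscaling_factor(area) * edge_fraction
    return ScaledRecord(
        individual_id=ib.individual_id,
        plot_id=plot.plot_id,
        growth_class=ib.growth_class,
        agb_standing=ib.agb_standing * w,
        agb_ex=ib.agb_ex * w,
        loss_by_agent={a: v * w for a, v in ib.loss_by_agent.items()},
        dead_stem_loss=ib.dead_stem_loss * w,
    )


@dataclass
class PlotSummary:
    """Per-plot totals, kg ha^-1, plus individual counts per growth class."""

    plot_id: str
    agb_standing: float = 0.0
    agb_ex: float = 0.0
    loss_by_agent: dict[str, float] = field(default_factory=dict)
    dead_stem_loss: float = 0.0
    n_by_class: dict[str, int] = field(default_factory=dict)

    @property
    def total_loss(self) -> float:
        return sum(self.loss_by_agent.values())

    @property
    def n_individuals(self) -> int:
        return sum(self.n_by_class.values())


def plot_summary(records: Sequence[ScaledRecord], plot_id: str | None = None) -> PlotSummary:
    """Field-wise sums of scaled records from a single plot.

    Conservation (agb_ex = standing + losses) is re-checked after summation.
    """
    plot_ids = {r.plot_id for r in records}
    if plot_id is None:
        if len(plot_ids) > 1:
            raise ValidationError(
                f"records from multiple plots in one summary call: {sorted(plot_ids)}"
            )
        plot_id = next(iter(plot_ids)) if plot_ids else "<empty>"
    elif plot_ids - {plot_id}:
        raise ValidationError(
            f"records from foreign plots {sorted(plot_ids - {plot_id})} "
            f"in summary of {plot_id}"
        )
    out = PlotSummary(plot_id=plot_id)
    for r in records:
        out.agb_standing += r.agb_standing
        out.agb_ex += r.agb_ex
        out.dead_stem_loss += r.dead_stem_loss
        for a, v in r.loss_by_agent.items():
            out.loss_by_agent[a] = out.loss_by_agent.get(a, 0.0) + v
        gc = r.growth_class.value
        out.n_by_class[gc] = out.n_by_class.get(gc, 0) + 1
    expected = out.agb_standing + out.total_loss
    scale = max(abs(out.agb_ex), abs(expected), 1e-300)
    if abs(out.agb_ex - expected) > 1e-9 * scale:
        raise ValidationError(
            f"plot {plot_id}: conservation violated after aggregation"
        )
    return out


def summarize_plots(
    results: Iterable[IndividualBiomass],
    individuals_edge: Mapping[str, tuple[str, float]],
    plots: Sequence[Plot],
) -> list[PlotSummary]:
    """Scale every individual and sum per plot.

    ``individuals_edge`` maps individual_id -> (plot_id, edge_fraction).
    Plots with no individuals yield all-zero summaries.
    """
    plot_by_id = {p.plot_id: p for p in plots}
    scaled: dict[str, list[ScaledRecord]] = {p.plot_id: [] for p in plots}
    for ib in results:
        plot_id, edge = individuals_edge[ib.individual_id]
        if plot_id not in plot_by_id:
            raise ConfigurationError(f"unknown plot {plot_id!r} for {ib.individual_id}")
        scaled[plot_id].append(scale_individual(ib, plot_by_id[plot_id], edge))
    return [plot_summary(scaled[p.plot_id], plot_id=p.plot_id) for p in plots]


@dataclass
class StandSummary:
    """Stratum-level (vegetation x density) means over replicate plots."""

    vegetation: str
    density_level: str
    n_plots: int
    mean_agb_standing: float
    sd_agb_standing: float
    mean_agb_ex: float
    sd_agb_ex: float
    mean_loss_by_agent: dict[str, float]
    agb_pot: float | None = None


def stand_summary(
    plot_summaries: Sequence[PlotSummary],
    plots: Sequence[Plot],
    design: StudyDesign | None = None,
    reference_level: str = "low",
    statistic: str = "mean",
    exclude_plots: Sequence[str] = (),
) -> list[StandSummary]:
    """Per-stratum means/sd and AGB_pot per vegetation type.

    AGB_pot is the central AGB_ex of the reference (least-disturbed) stratum
    of each vegetation type; ``statistic`` chooses mean (default) or median.
    ``exclude_plots`` drops user-identified outlier plots before summarising.
    """
    if statistic not in ("mean", "median"):
        raise ConfigurationError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    center = np.mean if statistic == "mean" else np.median
    plot_meta = {p.plot_id: p for p in plots}
    strata: dict[tuple[str, str], list[PlotSummary]] = {}
    for ps in plot_summaries:
        if ps.plot_id in exclude_plots:
            continue
        meta = plot_meta.get(ps.plot_id)
        if meta is None:
            raise ConfigurationError(f"no plot metadata for {ps.plot_id!r}")
        strata.setdefault((meta.vegetation, meta.density_level), []).append(ps)

    vegetations = {veg for veg, _ in strata}
    agb_pot: dict[str, float] = {}
    for veg in vegetations:
        ref = strata.get((veg, reference_level))
        if not ref:
            raise ConfigurationError(
                f"vegetation {veg!r}: reference stratum {reference_level!r} has no plots"
            )
        agb_pot[veg] = float(center([ps.agb_ex for ps in ref]))

    out = []
    for (veg, level), members in sorted(strata.items()):
        standing = np.array([ps.agb_standing for ps in members])
        ex = np.array([ps.agb_ex for ps in members])
        mean_loss = {
            a: float(np.mean([ps.loss_by_agent.get(a, 0.0) for ps in members]))
            for a in AGENTS
        }
        out.append(StandSummary(
            vegetation=veg,
            density_level=level,
            n_plots=len(members),
            mean_agb_standing=float(center(standing)),
            sd_agb_standing=float(np.std(standing, ddof=1)) if len(members) > 1 else 0.0,
            mean_agb_ex=float(center(ex)),
            sd_agb_ex=float(np.std(ex, ddof=1)) if len(members) > 1 else 0.0,
            mean_loss_by_agent=mean_loss,
            agb_pot=agb_pot[veg],
        ))
    return out


def plot_summaries_to_frame(summaries: Iterable[PlotSummary]) -> pd.DataFrame:
    rows = []
    for ps in summaries:
        row = {
            "plot_id": ps.plot_id,
            "agb_standing_kg_ha": ps.agb_standing,
            "agb_ex_kg_ha": ps.agb_ex,
        }
        for a in AGENTS:
            row[f"loss_{a}_kg_ha"] = ps.loss_by_agent.get(a, 0.0)
        row["dead_stem_loss_kg_ha"] = ps.dead_stem_loss
        row["n_individuals"] = ps.n_individuals
        rows.append(row)
    cols = (
        ["plot_id", "agb_standing_kg_ha", "agb_ex_kg_ha"]
        + [f"loss_{a}_kg_ha" for a in AGENTS]
        + ["dead_stem_loss_kg_ha", "n_individuals"]
    )
    return pd.DataFrame(rows, columns=cols)


def stand_summaries_to_frame(summaries: Iterable[StandSummary]) -> pd.DataFrame:
    rows = []
    for ss in summaries:
        row = {
            "vegetation": ss.vegetation,
            "density_level": ss.density_level,
            "n_plots": ss.n_plots,
            "mean_agb_standing_kg_ha": ss.mean_agb_standing,
            "sd_agb_standing_kg_ha": ss.sd_agb_standing,
            "mean_agb_ex_kg_ha": ss.mean_agb_ex,
            "sd_agb_ex_kg_ha": ss.sd_agb_ex,
            "agb_pot_kg_ha": ss.agb_pot,
        }
        for a in AGENTS:
            row[f"mean_loss_{a}_kg_ha"] = ss.mean_loss_by_agent.get(a, 0.0)
        rows.append(row)
    cols = (
        ["vegetation", "density_level", "n_plots",
         "mean_agb_standing_kg_ha", "sd_agb_standing_kg_ha",
         "mean_agb_ex_kg_ha", "sd_agb_ex_kg_ha", "agb_pot_kg_ha"]
        + [f"mean_loss_{a}_kg_ha" for a in AGENTS]
    )
    return pd.DataFrame(rows, columns=cols)


def losses_long_format(summaries: Iterable[PlotSummary]) -> pd.DataFrame:
    """Long-format per-plot loss table: plot_id, agent, loss_kg_ha."""
    rows = [
        {"plot_id": ps.plot_id, "agent": a, "loss_kg_ha": ps.loss_by_agent.get(a, 0.0)}
        for ps in summaries for a in AGENTS
    ]
    return pd.DataFrame(rows, columns=["plot_id", "agent", "loss_kg_ha"])
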