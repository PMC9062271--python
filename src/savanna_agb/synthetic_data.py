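"""Synthetic savanna inventories with known ground truth.

The generator emulates the study conditions of the field protocol: a
stratified design of 2 vegetation types x 3 elephant-density levels x 10
replicate plots of 1000 m², nested subplot areas per growth-class group
(juveniles on a fixed 100 m², saplings on 250-750 m², adult gullivers on
750-1000 m², healthy adults on the full plot), allometrically coherent tree
populations, per-agent disturbance losses with a fire-vs-elephant gradient
across density levels, topkilled dead stems, and wood samples per species.

Ground truth is produced by running the estimation protocol itself with the
generator's true allometry coefficients and true wood densities on the
emitted observables. End-to-end tests against this truth therefore verify
the protocol logic (classification, reconstruction chains, loss accounting,
upscaling) — not the external accuracy of the allometric models, for which
no independent truth exists. With all noise terms at zero, a blinded
pipeline run recovers the truth exactly because the calibration fits
recover the true coefficients exactly.

Randomness: one master seed; each plot draws from a deterministic substream
keyed by (seed, plot index), so partial regeneration is reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationModels
from .estimation import IndividualBiomass, estimate_individual, results_to_frame
from .inventory import (
    DamageAssessment,
    GrowthClass,
    Plot,
    StemMeasure,
    StudyDesign,
    WoodyIndividual,
    classify_growth_class,
    write_results,
)
from .wood_density import SpeciesDensityTable, WoodSample

#: Agents that can be responsible for topkill, with relative weights varied
#: by density level in the default regimes.
_TOPKILL_AGENTS = ("fire", "elephant", "woodcutting", "other")


@dataclass
class DisturbanceRegime:
    """Per-stratum disturbance intensities.

    ``mean_loss_by_agent``: mean loss *fraction* of living biomass per agent;
    ``affect_prob_by_agent``: chance that an agent touches an individual at
    all; ``topkill_probability``: share of adult gullivers whose main stem(s)
    are fully topkilled (subtype AG3); ``topkill_weights``: relative weights
    for attributing topkill to an agent.
    """

    mean_loss_by_agent: dict[str, float]
    affect_prob_by_agent: dict[str, float]
    topkill_probability: float = 0.25
    partial_dead_probability: float = 0.35
    topkill_weights: dict[str, float] = field(
        default_factory=lambda: {"fire": 1.0, "elephant": 1.0}
    )
    concentration: float = 12.0


def _default_regimes() -> dict[str, DisturbanceRegime]:
    # Fire losses decline as elephant density rises (less grass fuel under
    # heavy utilisation); elephant losses rise. Other agents stay flat.
    base_affect = {
        "fire": 0.7, "elephant": 0.7, "other_browsers": 0.35,
        "woodcutting": 0.10, "abiotic": 0.20, "other": 0.10,
    }
    means = {
        "low": {"fire": 0.14, "elephant": 0.03, "other_browsers": 0.03,
                "woodcutting": 0.03, "abiotic": 0.03, "other": 0.02},
        "medium": {"fire": 0.08, "elephant": 0.10, "other_browsers": 0.03,
                   "woodcutting": 0.02, "abiotic": 0.03, "other": 0.02},
        "high": {"fire": 0.03, "elephant": 0.20, "other_browsers": 0.03,
                 "woodcutting": 0.01, "abiotic": 0.03, "other": 0.02},
    }
    tk_prob = {"low": 0.15, "medium": 0.25, "high": 0.35}
    tk_weights = {
        "low": {"fire": 3.0, "elephant": 1.0},
        "medium": {"fire": 1.0, "elephant": 1.5},
        "high": {"fire": 0.5, "elephant": 3.0},
    }
    return {
        level: DisturbanceRegime(
            mean_loss_by_agent=means[level],
            affect_prob_by_agent=dict(base_affect),
            topkill_probability=tk_prob[level],
            topkill_weights=tk_weights[level],
        )
        for level in ("low", "medium", "high")
    }


#: Default species pool: (binomial label, true SWD g cm^-3). Typical
#: Zambezian woodland taxa with plausible density values.
DEFAULT_SPECIES_POOL: tuple[tuple[str, float], ...] = (
    ("Burkea africana", 0.60),
    ("Baikiaea plurijuga", 0.77),
    ("Terminalia sericea", 0.62),
    ("Combretum hereroense", 0.65),
    ("Dichrostachys cinerea", 0.74),
    ("Philenoptera nelsii", 0.56),
    ("Combretum imberbe", 0.93),
    ("Ochna pulchra", 0.58),
)


@dataclass
class SimulationConfig:
    """Everything the generator needs; the defaults are the study conditions."""

    design: StudyDesign = field(default_factory=StudyDesign)
    seed: int = 0
    species_pool: tuple[tuple[str, float], ...] = DEFAULT_SPECIES_POOL
    #: true allometry / reconstruction coefficients (a, b, s, t)
    true_a: float = 4.72595
    true_b: float = 0.63385
    true_s: float = 0.7968
    true_t: float = 0.2032
    #: stem density (individuals ha^-1) per class group, per vegetation type
    density_by_group: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "savanna": {"JU": 1200.0, "SA": 350.0, "AA": 60.0, "AG": 40.0},
        "woodland": {"JU": 900.0, "SA": 300.0, "AA": 120.0, "AG": 60.0},
    })
    regimes: dict[str, DisturbanceRegime] = field(default_factory=_default_regimes)
    #: adult DBH distribution: lognormal(log(median), sigma), cm
    dbh_median_cm: float = 18.0
    dbh_sigma: float = 0.45
    dbh_min_cm: float = 6.0
    #: subadult height ranges, cm
    juvenile_height_range: tuple[float, float] = (20.0, 150.0)
    sapling_height_range: tuple[float, float] = (150.0, 450.0)
    regrowth_height_range: tuple[float, float] = (60.0, 240.0)
    #: crown diameter link CD [m] = cd_coef * (h/100 [m])^cd_exp
    cd_coef: float = 0.5
    cd_exp: float = 0.85
    #: lognormal measurement-noise sigmas (0 = exact readings)
    noise_height: float = 0.0
    noise_circ: float = 0.0
    noise_cd: float = 0.0
    noise_wood: float = 0.0
    #: sampling quirks
    multi_stem_rate: float = 0.25
    missing_circ130_prob: float = 0.10
    alt_only_prob: float = 0.05
    taper_pair_prob: float = 0.30
    edge_prob: float = 0.05
    subadult_gulliver_fraction: float = 0.12
    #: subplot-area ranges, m²
    juvenile_area_m2: float = 100.0
    sapling_area_range: tuple[float, float] = (250.0, 750.0)
    gulliver_area_range: tuple[float, float] = (750.0, 1000.0)

    def true_models(self) -> CalibrationModels:
        return CalibrationModels(
            a=self.true_a, b=self.true_b, s=self.true_s, t=self.true_t,
            provenance="generator-truth",
        )

    def true_swd_table(self) -> SpeciesDensityTable:
        return SpeciesDensityTable(
            values={sp: (swd, 1) for sp, swd in self.species_pool}
        )


def zero_noise_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Config with all measurement noise off (exact readings)."""
    cfg = SimulationConfig(seed=seed, **overrides)
    cfg.noise_height = cfg.noise_circ = cfg.noise_cd = cfg.noise_wood = 0.0
    return cfg


def _lognoise(rng: np.random.Generator, sigma: float) -> float:
    return float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0


def generate_design(cfg: SimulationConfig) -> tuple[StudyDesign, list[Plot]]:
    """Lay out the stratified plot table with realized subplot areas."""
    rng = np.random.default_rng([cfg.seed, 0])
    plots = []
    k = 0
    for veg in cfg.design.vegetation_types:
        for level in cfg.design.density_levels:
            for i in range(cfg.design.plots_per_site):
                k += 1
                area = cfg.design.plot_area_m2
                sa = float(rng.uniform(*cfg.sapling_area_range))
                ag = float(min(rng.uniform(*cfg.gulliver_area_range), area))
                plots.append(Plot(
                    plot_id=f"P{k:03d}",
                    vegetation=veg,
                    density_level=level,
                    lat=float(-18.07 + rng.normal(0, 0.05)),
                    lon=float(23.42 + rng.normal(0, 0.05)),
                    plot_area_m2=area,
                    realized_area_by_class={
                        "JU": min(cfg.juvenile_area_m2, area),
                        "SA": min(sa, area),
                        "AA": area,
                        "AG": ag,
                    },
                ))
    return cfg.design, plots


# ---------------------------------------------------------------------------
# Individual-level simulation
# ---------------------------------------------------------------------------

def _natural_height(cfg: SimulationConfig, dbh: float, rng) -> float:
    return math.exp(cfg.true_a + cfg.true_b * math.log(dbh)) * _lognoise(rng, cfg.noise_height)

def _crown_pair(cfg: SimulationConfig, h_cm: float, rng) -> tuple[float, float]:
    cd = cfg.cd_coef * (h_cm / 100.0) ** cfg.cd_exp * _lognoise(rng, cfg.noise_cd)
    asym = rng.uniform(0.0, 0.25)
    return cd * (1.0 + asym), cd * (1.0 - asym)


def _make_adult_stems(cfg: SimulationConfig, n_stems: int, rng) -> tuple[list[StemMeasure], list[float]]:
    """Main stem carries basal + circ130 (sometimes an alt pair too);
    side stems are measured at the base only."""
    dbhs = np.maximum(
        rng.lognormal(math.log(cfg.dbh_median_cm), cfg.dbh_sigma, size=n_stems),
        cfg.dbh_min_cm,
    )
    dbhs = sorted((float(d) for d in dbhs), reverse=True)
    stems = []
    for i, dbh in enumerate(dbhs):
        basal = math.pi * dbh / cfg.true_s * _lognoise(rng, cfg.noise_circ)
        circ130 = math.pi * dbh * _lognoise(rng, cfg.noise_circ)
        alt_circ = alt_h = None
        if i == 0 and rng.random() < cfg.alt_only_prob:
            # heavily damaged base: only an alternative reading exists
            alt_h = float(rng.uniform(30.0, 110.0))
            alt_circ = basal * (130.0 - cfg.true_t * alt_h) / 130.0
            basal = circ130 = None
        else:
            if i == 0 and rng.random() < cfg.taper_pair_prob:
                alt_h = float(rng.uniform(30.0, 110.0))
                alt_circ = basal * (130.0 - cfg.true_t * alt_h) / 130.0 \
                    * _lognoise(rng, cfg.noise_circ)
            if i > 0 or rng.random() < cfg.missing_circ130_prob:
                circ130 = None
        stems.append(StemMeasure(
            basal_circ_cm=basal, circ130_cm=circ130,
            alt_circ_cm=alt_circ, alt_height_cm=alt_h,
        ))
    return stems, dbhs


def _draw_losses(
    regime: DisturbanceRegime, rng, cap: float = 0.99
) -> dict[str, float]:
    """Per-agent loss fractions; total rescaled below ``cap`` if exceeded."""
    out = {}
    c = regime.concentration
    for agent, mean in regime.mean_loss_by_agent.items():
        if mean <= 0:
            continue
        if rng.random() >= regime.affect_prob_by_agent.get(agent, 0.0):
            continue
        frac = float(rng.beta(mean * c, (1.0 - mean) * c))
        if frac > 0:
            out[agent] = frac
    total = sum(out.values())
    if total > cap:
        out = {a: v * 0.95 * cap / total for a, v in out.items()}
    return out


def _rescale_total(losses: dict[str, float], target: float) -> dict[str, float]:
    total = sum(losses.values())
    if total == 0:
        return losses
    return {a: v * target / total for a, v in losses.items()}


def _pick_topkill_agents(regime: DisturbanceRegime, rng) -> tuple[str, ...]:
    agents = list(regime.topkill_weights)
    w = np.array([regime.topkill_weights[a] for a in agents], dtype=float)
    w /= w.sum()
    first = str(rng.choice(agents, p=w))
    if len(agents) > 1 and rng.random() < 0.2:  # two joint agents
        others = [a for a in agents if a != first]
        wo = np.array([regime.topkill_weights[a] for a in others], dtype=float)
        return (first, str(rng.choice(others, p=wo / wo.sum())))
    return (first,)


def simulate_individuals(
    plot: Plot, cfg: SimulationConfig, rng: np.random.Generator
) -> list[WoodyIndividual]:
    """Undisturbed tree population of one plot (damage applied separately).

    Counts per class group are Poisson(density x realized subplot area);
    individuals destined for the adult-gulliver group are tagged via their
    comment field so that :func:`apply_disturbances` can force a coherent
    disturbance history onto them.
    """
    dens = cfg.density_by_group[plot.vegetation]
    species = [sp for sp, _ in cfg.species_pool]
    individuals = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"{plot.plot_id}-{counter:04d}"

    for group in ("JU", "SA", "AA", "AG"):
        area = plot.realized_area_by_class[group]
        n = int(rng.poisson(dens.get(group, 0.0) * area / 10_000.0))
        for _ in range(n):
            sp = str(rng.choice(species))
            edge = 0.5 if rng.random() < cfg.edge_prob else 1.0
            if group in ("JU", "SA"):
                lo, hi = (
                    cfg.juvenile_height_range if group == "JU"
                    else cfg.sapling_height_range
                )
                h = float(rng.uniform(lo, hi))
                if group == "SA":
                    h = min(h, hi - 1e-6)
                cd1, cd2 = _crown_pair(cfg, h, rng)
                individuals.append(WoodyIndividual(
                    individual_id=new_id(), plot_id=plot.plot_id, species=sp,
                    height_cm=h, crown_diameter_1_m=cd1, crown_diameter_2_m=cd2,
                    edge_fraction=edge,
                    damage=DamageAssessment(comment=f"path:{group}"),
                ))
            else:
                n_stems = 1 + int(rng.binomial(2, cfg.multi_stem_rate))
                if group == "AG":
                    n_stems = max(n_stems, 1)
                stems, dbhs = _make_adult_stems(cfg, n_stems, rng)
                h = _natural_height(cfg, dbhs[0], rng)
                individuals.append(WoodyIndividual(
                    individual_id=new_id(), plot_id=plot.plot_id, species=sp,
                    height_cm=h, stems=stems, edge_fraction=edge,
                    damage=DamageAssessment(comment=f"path:{group}"),
                ))
    return individuals


def apply_disturbances(
    individuals: Sequence[WoodyIndividual],
    regime: DisturbanceRegime,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> list[WoodyIndividual]:
    """Draw per-agent losses, topkill dead stems, and gulliver conversions.

    The intended class-group path recorded at simulation time is honoured:
    JU/SA/AA-path individuals stay below the 30% gulliver threshold unless
    tagged as subadult gullivers; AG-path adults are forced into one of the
    AG subtypes (heavy crown loss, partial stem death, or full topkill with
    shrub-like regrowth).
    """
    out = []
    for ind in individuals:
        path = ind.damage.comment.removeprefix("path:")
        losses = _draw_losses(regime, rng)
        total = sum(losses.values())

        if path in ("JU", "SA"):
            if rng.random() < cfg.subadult_gulliver_fraction:
                losses = _rescale_total(losses, float(rng.uniform(0.35, 0.8))) \
                    if losses else {"fire": float(rng.uniform(0.35, 0.8))}
            elif total >= 0.295:
                losses = _rescale_total(losses, 0.25)
        elif path == "AA":
            if total >= 0.295:
                losses = _rescale_total(losses, 0.25)
        elif path == "AG":
            u = rng.random()
            if u < regime.topkill_probability:
                ind = _topkill(ind, regime, cfg, rng)
                losses = _draw_losses(regime, rng)
                if sum(losses.values()) >= 0.295:
                    losses = _rescale_total(losses, 0.25)
            elif u < regime.topkill_probability + regime.partial_dead_probability \
                    and len(ind.stems) >= 2:
                ind = _partial_topkill(ind, regime, cfg, rng)
                if rng.random() < 0.5:  # AG2b: heavy losses on living crowns
                    target = float(rng.uniform(0.32, 0.8))
                    losses = _rescale_total(losses, target) if losses \
                        else {"elephant": target}
                    ind.height_cm *= float(rng.uniform(0.6, 1.0))
                elif sum(losses.values()) >= 0.295:  # AG2a: light losses
                    losses = _rescale_total(losses, 0.25)
            else:
                # AG1: regular form, heavy crown loss, possibly shortened
                target = float(rng.uniform(0.32, 0.8))
                losses = _rescale_total(losses, target) if losses \
                    else {"elephant": target}
                ind.height_cm *= float(rng.uniform(0.6, 1.0))
        ind.damage = DamageAssessment(
            loss_percent_by_agent={a: v * 100.0 for a, v in losses.items()}
        )
        out.append(ind)
    return out


def _topkill(ind, regime, cfg, rng) -> WoodyIndividual:
    """Full topkill: all adult stems die; shrub-like regrowth from the roots."""
    dead = []
    for s in ind.stems:
        basal = s.basal_circ_cm
        alt_circ = alt_h = None
        if basal is None and s.alt_circ_cm is not None:
            alt_circ, alt_h = s.alt_circ_cm, s.alt_height_cm
        elif rng.random() < 0.1:
            alt_h = float(rng.uniform(30.0, 110.0))
            alt_circ = basal * (130.0 - cfg.true_t * alt_h) / 130.0
            basal = None
        dead.append(StemMeasure(
            basal_circ_cm=basal, alt_circ_cm=alt_circ, alt_height_cm=alt_h,
            is_dead=True, topkill_agents=_pick_topkill_agents(regime, rng),
        ))
    h = float(rng.uniform(*cfg.regrowth_height_range))
    cd1, cd2 = _crown_pair(cfg, h, rng)
    ind.stems = dead
    ind.height_cm = h
    ind.crown_diameter_1_m, ind.crown_diameter_2_m = cd1, cd2
    return ind


def _partial_topkill(ind, regime, cfg, rng) -> WoodyIndividual:
    """Kill a proper subset of stems; the individual keeps adult living stems."""
    n = len(ind.stems)
    n_dead = int(rng.integers(1, n))
    idx = set(rng.choice(n, size=n_dead, replace=False).tolist())
    new_stems = []
    for i, s in enumerate(ind.stems):
        if i in idx:
            basal = s.basal_circ_cm
            alt_circ = alt_h = None
            if basal is None and s.alt_circ_cm is not None:
                alt_circ, alt_h = s.alt_circ_cm, s.alt_height_cm
            new_stems.append(StemMeasure(
                basal_circ_cm=basal, alt_circ_cm=alt_circ, alt_height_cm=alt_h,
                is_dead=True, topkill_agents=_pick_topkill_agents(regime, rng),
            ))
        else:
            new_stems.append(s)
    ind.stems = new_stems
    return ind


# ---------------------------------------------------------------------------
# Wood samples and study assembly
# ---------------------------------------------------------------------------

def simulate_wood_samples(
    species_pool: Sequence[tuple[str, float]],
    rng: np.random.Generator,
    noise: float = 0.0,
) -> list[WoodSample]:
    """2-10 wood samples per species, dimensionally consistent with true SWD."""
    samples = []
    for sp, swd in species_pool:
        n = int(rng.integers(2, 11))
        for j in range(n):
            length = float(rng.uniform(4.0, 10.0))
            if rng.random() < 0.5:  # increment core (fixed bore)
                base_d = 0.515
            else:                   # sawn stem piece
                base_d = float(rng.uniform(1.0, 3.0))
            diameters = tuple(
                base_d * _lognoise(rng, noise) for _ in range(5)
            )
            d_mean = sum(diameters) / 5.0
            volume = math.pi * (d_mean / 2.0) ** 2 * length
            mass = swd * volume * _lognoise(rng, noise)
            samples.append(WoodSample(
                species=sp, sample_id=f"{sp.split()[0][:4]}-{j:02d}",
                length_cm=length, diameters_cm=diameters, dry_mass_g=mass,
            ))
    return samples


@dataclass
class SimulatedStudy:
    """A complete synthetic study: observables plus protocol ground truth."""

    config: SimulationConfig
    design: StudyDesign
    plots: list[Plot]
    individuals: list[WoodyIndividual]
    wood_samples: list[WoodSample]
    truth: list[IndividualBiomass]

    def truth_frame(self) -> pd.DataFrame:
        df = results_to_frame(self.truth)
        cls = {i.individual_id: i for i in self.individuals}
        df.insert(1, "plot_id", [cls[i].plot_id for i in df["individual_id"]])
        df.insert(2, "edge_fraction", [cls[i].edge_fraction for i in df["individual_id"]])
        return df


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate design, populations, disturbances, wood samples and truth."""
    design, plots = generate_design(cfg)
    true_models = cfg.true_models()
    true_swd = cfg.true_swd_table()
    individuals: list[WoodyIndividual] = []
    truth: list[IndividualBiomass] = []
    for k, plot in enumerate(plots, start=1):
        rng = np.random.default_rng([cfg.seed, k])
        pop = simulate_individuals(plot, cfg, rng)
        pop = apply_disturbances(pop, cfg.regimes[plot.density_level], cfg, rng)
        for ind in pop:
            ind.growth_class = classify_growth_class(ind)
            truth.append(estimate_individual(ind, true_swd, true_models))
            # blind the emitted record: class is re-derived by the pipeline
            ind.growth_class = None
        individuals.extend(pop)
    wood_rng = np.random.default_rng([cfg.seed, 1_000_003])
    samples = simulate_wood_samples(cfg.species_pool, wood_rng, cfg.noise_wood)
    return SimulatedStudy(
        config=cfg, design=design, plots=plots,
        individuals=individuals, wood_samples=samples, truth=truth,
    )


def emit_field_tables(study: SimulatedStudy, directory: str | Path) -> dict[str, Path]:
    """Write observable CSVs plus the ground-truth table for test oracles.

    The observables carry no AGB columns — estimation stays blinded.
    """
    directory = Path(directory)
    paths = write_results(study.individuals, study.plots, directory)
    from .wood_density import write_wood_samples
    paths["wood_samples"] = directory / "wood_samples.csv"
    write_wood_samples(study.wood_samples, paths["wood_samples"])
    paths["ground_truth"] = directory / "ground_truth.csv"
    study.truth_frame().to_csv(paths["ground_truth"], index=False, float_format="%.17g")
    cfg = dataclasses.asdict(study.config)
    paths["config"] = directory / "config_resolved.json"
    import json
    paths["config"].write_text(json.dumps(cfg, indent=2, default=str) + "\n")
    return paths
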