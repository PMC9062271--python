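"""Domain types, growth-class classification, and tabular I/O for woody inventories.

Canonical units: heights and circumferences in cm, crown diameters in m,
areas in m². All unit conversions required by the allometric models happen
inside the allometry functions, never here.

An inventory is three tables — individuals, stems, plots — mirroring a
field spreadsheet. The canonical on-disk dialect is UTF-8 CSV; an XLSX
adapter reads multi-sheet field workbooks via an explicit column mapping.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import FormatError, UnclassifiableError, ValidationError

#: Disturbance-agent vocabulary. Loss percentages are recorded per agent;
#: anything else observed in the field is mapped onto "other".
AGENTS = ("elephant", "fire", "other_browsers", "woodcutting", "abiotic", "other")

#: Maximum total biomass loss assignable to a living individual. Total
#: topkill is scored 99%, never 100%, so a living remainder always exists.
MAX_TOTAL_LOSS_PERCENT = 99.0

#: Adult-size criterion: a stem is adult-sized when its basal circumference
#: strictly exceeds this many cm.
DEFAULT_ADULT_CIRC_THRESHOLD = 15.0

#: Damage threshold separating gullivers (heavily damaged individuals whose
#: height predicts neither age nor biomass) from regular growth classes.
DEFAULT_GULLIVER_LOSS_THRESHOLD = 30.0

#: Height boundary between juveniles and saplings/shrubs, cm. Site-specific;
#: the default is a pragmatic choice, not a universal constant.
DEFAULT_JUVENILE_HEIGHT_THRESHOLD = 150.0


class GrowthClass(str, Enum):
    """Growth classes driving the per-individual estimation workflow.

    Size tiers: juvenile (JU/GJ), sapling/shrub (SA/GS), adult (AA/AG*).
    The G-prefixed and AG classes are "gullivers": individuals with >= 30%
    biomass loss. Adult-sized gullivers split into four subtypes by the mix
    of living and dead adult-sized stems.
    """

    JU = "JU"      #: juvenile, lightly damaged
    SA = "SA"      #: sapling / shrub, lightly damaged
    AA = "AA"      #: adult, lightly damaged (non-gulliver)
    GJ = "GJ"      #: juvenile-sized gulliver
    GS = "GS"      #: sapling-sized gulliver
    AG1 = "AG1"    #: adult gulliver: living stems only, heavy crown losses
    AG2a = "AG2a"  #: adult gulliver: dead + lightly damaged living stems
    AG2b = "AG2b"  #: adult gulliver: dead + heavily damaged living stems
    AG3 = "AG3"    #: adult gulliver: topkilled main stem, shrub-like regrowth


#: Subplot-area group for upscaling: juveniles, saplings, healthy adults and
#: adult gullivers are recorded on different nested subplot areas.
AREA_GROUPS = ("JU", "SA", "AA", "AG")

_AREA_GROUP_OF = {
    GrowthClass.JU: "JU", GrowthClass.GJ: "JU",
    GrowthClass.SA: "SA", GrowthClass.GS: "SA",
    GrowthClass.AA: "AA",
    GrowthClass.AG1: "AG", GrowthClass.AG2a: "AG",
    GrowthClass.AG2b: "AG", GrowthClass.AG3: "AG",
}


def area_group(gc: GrowthClass) -> str:
    """Return the nested-subplot area group a growth class is recorded on."""
    return _AREA_GROUP_OF[GrowthClass(gc)]


@dataclass
class StudyDesign:
    """Stratified sampling design: vegetation types x disturbance levels."""

    vegetation_types: tuple[str, ...] = ("savanna", "woodland")
    density_levels: tuple[str, ...] = ("low", "medium", "high")
    plots_per_site: int = 10
    plot_area_m2: float = 1000.0

    def __post_init__(self) -> None:
        if self.plots_per_site < 1:
            raise ValidationError("plots_per_site must be >= 1")
        if self.plot_area_m2 <= 0:
            raise ValidationError("plot_area_m2 must be > 0")

    @property
    def n_sites(self) -> int:
        return len(self.vegetation_types) * len(self.density_levels)

    @property
    def n_plots(self) -> int:
        return self.n_sites * self.plots_per_site


@dataclass
class Plot:
    """One observation plot with its realized sampling areas per class group."""

    plot_id: str
    vegetation: str = ""
    density_level: str = ""
    lat: float | None = None
    lon: float | None = None
    plot_area_m2: float = 1000.0
    realized_area_by_class: dict[str, float] = field(default_factory=dict)

    def realized_area(self, gc: GrowthClass) -> float | None:
        return self.realized_area_by_class.get(area_group(gc))

    def validate(self) -> list[str]:
        out = []
        if self.plot_area_m2 <= 0:
            out.append(f"plot {self.plot_id}: plot_area_m2 must be > 0")
        for group, area in self.realized_area_by_class.items():
            if not 0 < area <= self.plot_area_m2:
                out.append(
                    f"plot {self.plot_id}: realized area for {group} "
                    f"({area} m2) outside (0, {self.plot_area_m2}]"
                )
        return out


@dataclass
class StemMeasure:
    """Circumference readings for one adult-sized stem.

    DBH is derivable from ``circ130_cm``; where breast-height measurement was
    impossible, ``basal_circ_cm`` or the alternative pair
    (``alt_circ_cm`` at height ``alt_height_cm``) supports reconstruction.
    Dead stems record the presumed topkill agent(s) — at most two.
    """

    basal_circ_cm: float | None = None
    circ130_cm: float | None = None
    alt_circ_cm: float | None = None
    alt_height_cm: float | None = None
    is_dead: bool = False
    topkill_agents: tuple[str, ...] = ()

    def validate(self) -> list[str]:
        out = []
        for name in ("basal_circ_cm", "circ130_cm", "alt_circ_cm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                out.append(f"{name} must be > 0, got {v}")
        if (self.alt_circ_cm is None) != (self.alt_height_cm is None):
            out.append("alt_circ_cm and alt_height_cm must be given together")
        if self.alt_height_cm is not None:
            # the taper reconstruction denominator 130 - t*hx must stay
            # positive at the default taper coefficient
            if not 0 <= self.alt_height_cm < 130.0 / 0.2032:
                out.append(
                    f"alt_height_cm {self.alt_height_cm} outside [0, {130.0 / 0.2032:.1f})"
                )
        if self.is_dead and not self.topkill_agents:
            out.append("dead stem must carry at least one topkill agent")
        if len(self.topkill_agents) > 2:
            out.append("at most two joint topkill agents allowed")
        if self.basal_circ_cm is None and self.circ130_cm is None and self.alt_circ_cm is None:
            out.append("stem has no circumference measurement at all")
        return out

    def size_circ(self) -> float | None:
        """Circumference used for the adult-size test (basal preferred)."""
        for v in (self.basal_circ_cm, self.circ130_cm, self.alt_circ_cm):
            if v is not None:
                return v
        return None


def normalize_agent(agent: str) -> str:
    """Map a free-text agent label onto the fixed vocabulary.

    Unknown agents go to "other" with a warning; they are never dropped.
    """
    a = agent.strip().lower().replace(" ", "_")
    if a in ("browser", "browsers", "other_browser"):
        a = "other_browsers"
    if a not in AGENTS:
        warnings.warn(f"unknown disturbance agent {agent!r} mapped to 'other'")
        return "other"
    return a


@dataclass
class DamageAssessment:
    """Visually estimated percentage of AGB lost, per disturbance agent.

    Percentages refer to the living part of the individual only; dead
    adult-sized stems are recorded separately on their StemMeasure and are
    not included here. Totals are capped at 99% — total topkill still
    leaves a living remainder by definition.
    """

    loss_percent_by_agent: dict[str, float] = field(default_factory=dict)
    comment: str = ""

    def __post_init__(self) -> None:
        self.loss_percent_by_agent = {
            normalize_agent(k): float(v)
            for k, v in self.loss_percent_by_agent.items()
            if v not in (None, 0, 0.0)
        }

    @property
    def total_percent(self) -> float:
        return sum(self.loss_percent_by_agent.values())

    def validate(self) -> list[str]:
        out = []
        for agent, pct in self.loss_percent_by_agent.items():
            if not 0 <= pct <= MAX_TOTAL_LOSS_PERCENT:
                out.append(f"loss for {agent} ({pct}%) outside [0, 99]")
        total = self.total_percent
        if total > MAX_TOTAL_LOSS_PERCENT:
            out.append(f"sum of losses {total:g} > {MAX_TOTAL_LOSS_PERCENT:g}")
        return out


@dataclass
class WoodyIndividual:
    """One tree or shrub record: size proxies, stems, damage, growth class."""

    individual_id: str
    plot_id: str
    species: str
    height_cm: float
    crown_diameter_1_m: float | None = None
    crown_diameter_2_m: float | None = None
    stems: list[StemMeasure] = field(default_factory=list)
    damage: DamageAssessment = field(default_factory=DamageAssessment)
    growth_class: GrowthClass | None = None
    edge_fraction: float = 1.0

    @property
    def mean_crown_diameter_m(self) -> float | None:
        """Arithmetic mean of the two orthogonal crown-diameter readings."""
        if self.crown_diameter_1_m is None or self.crown_diameter_2_m is None:
            return None
        return 0.5 * (self.crown_diameter_1_m + self.crown_diameter_2_m)

    def living_stems(self) -> list[StemMeasure]:
        return [s for s in self.stems if not s.is_dead]

    def dead_stems(self) -> list[StemMeasure]:
        return [s for s in self.stems if s.is_dead]


def validate_individual(ind: WoodyIndividual) -> list[str]:
    """Check all record-level invariants; return violations, never raise."""
    out = []
    if ind.height_cm is None or not ind.height_cm > 0:
        out.append(f"{ind.individual_id}: height_cm must be > 0")
    for name in ("crown_diameter_1_m", "crown_diameter_2_m"):
        v = getattr(ind, name)
        if v is not None and v <= 0:
            out.append(f"{ind.individual_id}: {name} must be > 0, got {v}")
    if not 0 < ind.edge_fraction <= 1:
        out.append(f"{ind.individual_id}: edge_fraction must be in (0, 1]")
    for i, stem in enumerate(ind.stems):
        out.extend(f"{ind.individual_id} stem {i}: {v}" for v in stem.validate())
    out.extend(f"{ind.individual_id}: {v}" for v in ind.damage.validate())
    return out


def classify_growth_class(
    ind: WoodyIndividual,
    adult_circ_threshold: float = DEFAULT_ADULT_CIRC_THRESHOLD,
    gulliver_loss_threshold: float = DEFAULT_GULLIVER_LOSS_THRESHOLD,
    juvenile_height_threshold: float = DEFAULT_JUVENILE_HEIGHT_THRESHOLD,
) -> GrowthClass:
    """Assign the growth class that selects the estimation workflow.

    An individual is adult-sized when at least one stem has a circumference
    strictly above ``adult_circ_threshold`` (default 15 cm at the base; a
    stem of exactly 15 cm is not adult-sized). Heavy damage — total recorded
    loss at or above ``gulliver_loss_threshold`` percent — turns each size
    tier into the corresponding gulliver class. Adult gullivers subdivide by
    their mix of living and dead adult-sized stems; AG3 (topkilled main
    stem, shrub-like regrowth) needs crown diameters for the living part.
    """
    if ind.height_cm is None or not ind.height_cm > 0:
        raise ValidationError(f"{ind.individual_id}: missing or non-positive height")
    for thr in (adult_circ_threshold, gulliver_loss_threshold, juvenile_height_threshold):
        if thr <= 0:
            raise ValidationError("classification thresholds must be > 0")

    def adult_sized(stem: StemMeasure) -> bool:
        c = stem.size_circ()
        return c is not None and c > adult_circ_threshold

    living_adult = any(adult_sized(s) for s in ind.living_stems())
    dead_adult = any(adult_sized(s) for s in ind.dead_stems())
    heavy = ind.damage.total_percent >= gulliver_loss_threshold

    if dead_adult and not living_adult:
        if ind.mean_crown_diameter_m is None:
            missing = [
                n for n in ("crown_diameter_1_m", "crown_diameter_2_m")
                if getattr(ind, n) is None
            ]
            raise UnclassifiableError(
                f"{ind.individual_id}: dead adult-sized stem but no living-part "
                f"proxies; missing {', '.join(missing)}",
                missing=missing,
            )
        return GrowthClass.AG3
    if living_adult and dead_adult:
        return GrowthClass.AG2b if heavy else GrowthClass.AG2a
    if living_adult:
        return GrowthClass.AG1 if heavy else GrowthClass.AA
    # no adult-sized stems at all: subadult tiers by height
    if ind.height_cm >= juvenile_height_threshold:
        return GrowthClass.GS if heavy else GrowthClass.SA
    return GrowthClass.GJ if heavy else GrowthClass.JU


# ---------------------------------------------------------------------------
# Tabular I/O — canonical CSV dialect
# ---------------------------------------------------------------------------

INDIVIDUAL_COLUMNS = [
    "individual_id", "plot_id", "species", "growth_class", "height_cm",
    "cd1_m", "cd2_m", "edge_fraction",
    "loss_elephant", "loss_fire", "loss_browsers", "loss_woodcutting",
    "loss_abiotic", "loss_other", "comment",
]
STEM_COLUMNS = [
    "individual_id", "stem_id", "basal_circ_cm", "circ130_cm",
    "alt_circ_cm", "alt_height_cm", "is_dead", "topkill_agent_1", "topkill_agent_2",
]
PLOT_COLUMNS = [
    "plot_id", "vegetation", "density_level", "lat", "lon", "plot_area_m2",
    "area_JU", "area_SA", "area_AA", "area_AG",
]

_LOSS_COL_OF_AGENT = {
    "elephant": "loss_elephant",
    "fire": "loss_fire",
    "other_browsers": "loss_browsers",
    "woodcutting": "loss_woodcutting",
    "abiotic": "loss_abiotic",
    "other": "loss_other",
}
_AGENT_OF_LOSS_COL = {v: k for k, v in _LOSS_COL_OF_AGENT.items()}


def _opt(v):
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def individuals_to_frames(
    individuals: Iterable[WoodyIndividual],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize individuals to the canonical (individuals, stems) tables."""
    ind_rows, stem_rows = [], []
    for ind in individuals:
        row = {
            "individual_id": ind.individual_id,
            "plot_id": ind.plot_id,
            "species": ind.species,
            "growth_class": ind.growth_class.value if ind.growth_class else "",
            "height_cm": ind.height_cm,
            "cd1_m": ind.crown_diameter_1_m,
            "cd2_m": ind.crown_diameter_2_m,
            "edge_fraction": ind.edge_fraction,
            "comment": ind.damage.comment,
        }
        for agent, col in _LOSS_COL_OF_AGENT.items():
            row[col] = ind.damage.loss_percent_by_agent.get(agent, 0.0)
        ind_rows.append(row)
        for j, s in enumerate(ind.stems):
            agents = list(s.topkill_agents) + ["", ""]
            stem_rows.append({
                "individual_id": ind.individual_id,
                "stem_id": j,
                "basal_circ_cm": s.basal_circ_cm,
                "circ130_cm": s.circ130_cm,
                "alt_circ_cm": s.alt_circ_cm,
                "alt_height_cm": s.alt_height_cm,
                "is_dead": int(s.is_dead),
                "topkill_agent_1": agents[0],
                "topkill_agent_2": agents[1],
            })
    ind_df = pd.DataFrame(ind_rows, columns=INDIVIDUAL_COLUMNS)
    stem_df = pd.DataFrame(stem_rows, columns=STEM_COLUMNS)
    return ind_df, stem_df


def plots_to_frame(plots: Iterable[Plot]) -> pd.DataFrame:
    rows = []
    for p in plots:
        row = {
            "plot_id": p.plot_id, "vegetation": p.vegetation,
            "density_level": p.density_level, "lat": p.lat, "lon": p.lon,
            "plot_area_m2": p.plot_area_m2,
        }
        for g in AREA_GROUPS:
            row[f"area_{g}"] = p.realized_area_by_class.get(g)
        rows.append(row)
    return pd.DataFrame(rows, columns=PLOT_COLUMNS)


def frames_to_individuals(
    ind_df: pd.DataFrame, stem_df: pd.DataFrame
) -> list[WoodyIndividual]:
    missing = [c for c in INDIVIDUAL_COLUMNS if c not in ind_df.columns]
    if missing:
        raise FormatError(f"individuals table missing columns: {', '.join(missing)}")
    missing = [c for c in STEM_COLUMNS if c not in stem_df.columns]
    if missing:
        raise FormatError(f"stems table missing columns: {', '.join(missing)}")

    stems_by_ind: dict[str, list[StemMeasure]] = {}
    for _, r in stem_df.iterrows():
        agents = tuple(
            normalize_agent(str(a))
            for a in (r["topkill_agent_1"], r["topkill_agent_2"])
            if isinstance(a, str) and a.strip()
        )
        stems_by_ind.setdefault(str(r["individual_id"]), []).append(StemMeasure(
            basal_circ_cm=_opt(r["basal_circ_cm"]),
            circ130_cm=_opt(r["circ130_cm"]),
            alt_circ_cm=_opt(r["alt_circ_cm"]),
            alt_height_cm=_opt(r["alt_height_cm"]),
            is_dead=bool(int(r["is_dead"])),
            topkill_agents=agents,
        ))

    individuals = []
    for _, r in ind_df.iterrows():
        losses = {}
        for col, agent in _AGENT_OF_LOSS_COL.items():
            v = _opt(r[col])
            if v:
                losses[agent] = v
        gc = r["growth_class"]
        gc = GrowthClass(gc) if isinstance(gc, str) and gc.strip() else None
        iid = str(r["individual_id"])
        individuals.append(WoodyIndividual(
            individual_id=iid,
            plot_id=str(r["plot_id"]),
            species=str(r["species"]),
            height_cm=float(r["height_cm"]),
            crown_diameter_1_m=_opt(r["cd1_m"]),
            crown_diameter_2_m=_opt(r["cd2_m"]),
            stems=stems_by_ind.get(iid, []),
            damage=DamageAssessment(
                loss_percent_by_agent=losses,
                comment="" if pd.isna(r["comment"]) else str(r["comment"]),
            ),
            growth_class=gc,
            edge_fraction=float(r["edge_fraction"]),
        ))
    return individuals


def frame_to_plots(plot_df: pd.DataFrame) -> list[Plot]:
    missing = [c for c in PLOT_COLUMNS if c not in plot_df.columns]
    if missing:
        raise FormatError(f"plots table missing columns: {', '.join(missing)}")
    plots = []
    for _, r in plot_df.iterrows():
        areas = {}
        for g in AREA_GROUPS:
            v = _opt(r[f"area_{g}"])
            if v is not None:
                areas[g] = v
        plots.append(Plot(
            plot_id=str(r["plot_id"]),
            vegetation="" if pd.isna(r["vegetation"]) else str(r["vegetation"]),
            density_level="" if pd.isna(r["density_level"]) else str(r["density_level"]),
            lat=_opt(r["lat"]), lon=_opt(r["lon"]),
            plot_area_m2=float(r["plot_area_m2"]),
            realized_area_by_class=areas,
        ))
    return plots


def write_results(
    individuals: Iterable[WoodyIndividual],
    plots: Iterable[Plot],
    directory: str | Path,
) -> dict[str, Path]:
    """Write the canonical three-table CSV inventory into ``directory``.

    Deterministic column order; full float precision so that a read/write
    round trip is the identity on validated records.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ind_df, stem_df = individuals_to_frames(individuals)
    plot_df = plots_to_frame(plots)
    paths = {
        "individuals": directory / "individuals.csv",
        "stems": directory / "stems.csv",
        "plots": directory / "plots.csv",
    }
    ind_df.to_csv(paths["individuals"], index=False, float_format="%.17g")
    stem_df.to_csv(paths["stems"], index=False, float_format="%.17g")
    plot_df.to_csv(paths["plots"], index=False, float_format="%.17g")
    return paths


def read_inventory(
    source: str | Path,
    dialect: str = "canonical_csv",
    column_mapping: Mapping[str, Mapping[str, str]] | None = None,
) -> tuple[list[WoodyIndividual], list[Plot]]:
    """Read an inventory from disk.

    dialect "canonical_csv": ``source`` is a directory holding
    individuals.csv, stems.csv and plots.csv in the canonical schema.
    dialect "mendeley_xlsx": ``source`` is a multi-sheet field workbook;
    ``column_mapping`` maps sheet/column names onto the canonical ones
    (best effort — field spreadsheets do not share a fixed layout).
    """
    source = Path(source)
    if dialect == "canonical_csv":
        if not source.is_dir():
            raise FormatError(f"{source} is not a directory of canonical CSVs")
        ind_df = pd.read_csv(source / "individuals.csv", dtype={"individual_id": str, "plot_id": str}, float_precision="round_trip")
        stem_df = pd.read_csv(source / "stems.csv", dtype={"individual_id": str}, float_precision="round_trip")
        plot_df = pd.read_csv(source / "plots.csv", dtype={"plot_id": str}, float_precision="round_trip")
        return frames_to_individuals(ind_df, stem_df), frame_to_plots(plot_df)
    if dialect == "mendeley_xlsx":
        return _read_xlsx(source, column_mapping)
    raise FormatError(f"unknown dialect {dialect!r}")


#: Default sheet/column mapping for a field workbook laid out like the
#: deposited dataset (sheets: data prop / SWD / raw dendrometrics /
#: coordinates). Column names are remapped onto the canonical schema.
DEFAULT_XLSX_MAPPING: dict[str, dict[str, str]] = {
    "sheets": {
        "individuals": "raw dendrometrics",
        "stems": "stems",
        "plots": "coordinates",
    },
    "individuals": {c: c for c in INDIVIDUAL_COLUMNS},
    "stems": {c: c for c in STEM_COLUMNS},
    "plots": {c: c for c in PLOT_COLUMNS},
}


def _read_xlsx(path: Path, column_mapping=None) -> tuple[list[WoodyIndividual], list[Plot]]:
    mapping = {**DEFAULT_XLSX_MAPPING, **(column_mapping or {})}
    sheets = mapping["sheets"]
    book = pd.read_excel(path, sheet_name=None)

    def pick(kind: str) -> pd.DataFrame:
        name = sheets[kind]
        if name not in book:
            raise FormatError(
                f"workbook {path.name} has no sheet {name!r}; found {sorted(book)}"
            )
        df = book[name].rename(columns={v: k for k, v in mapping[kind].items()})
        return df

    ind_df, stem_df, plot_df = pick("individuals"), pick("stems"), pick("plots")
    for df, cols in ((ind_df, INDIVIDUAL_COLUMNS), (stem_df, STEM_COLUMNS), (plot_df, PLOT_COLUMNS)):
        for c in cols:
            if c not in df.columns:
                df[c] = None
    return frames_to_individuals(ind_df, stem_df), frame_to_plots(plot_df)
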