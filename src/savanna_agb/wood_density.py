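"""Specific wood density (SWD) from core / stem-piece measurements.

SWD (also called wood specific gravity) is oven-dry mass per fresh volume,
g cm^-3. Fresh volume is taken as a cylinder whose diameter is the mean of
five caliper readings along the sample. Species means feed the stem-based
allometric model; species missing from the local table fall back to a genus
mean, then to an optional global default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .exceptions import SwdLookupError, ValidationError

#: Sanity ceiling for SWD values; the densest known woods are ~1.4 g cm^-3,
#: so anything above this is a data-entry error.
MAX_SWD = 1.5


@dataclass
class WoodSample:
    """One wood core or cylindrical stem piece, bark removed."""

    species: str
    sample_id: str
    length_cm: float
    diameters_cm: tuple[float, ...]
    dry_mass_g: float

    def validate(self) -> list[str]:
        out = []
        if self.length_cm <= 0:
            out.append(f"{self.sample_id}: length_cm must be > 0")
        if len(self.diameters_cm) != 5:
            out.append(f"{self.sample_id}: exactly 5 diameter readings required, "
                       f"got {len(self.diameters_cm)}")
        if any(d <= 0 for d in self.diameters_cm):
            out.append(f"{self.sample_id}: all diameters must be > 0")
        if self.dry_mass_g <= 0:
            out.append(f"{self.sample_id}: dry_mass_g must be > 0")
        return out


def _check(sample: WoodSample) -> None:
    violations = sample.validate()
    if violations:
        raise ValidationError("; ".join(violations))


def sample_volume(sample: WoodSample) -> float:
    """Fresh volume (cm^3): cylinder with the mean of the 5 diameter readings."""
    _check(sample)
    d_mean = sum(sample.diameters_cm) / len(sample.diameters_cm)
    return math.pi * (d_mean / 2.0) ** 2 * sample.length_cm


def compute_swd(sample: WoodSample) -> float:
    """Specific wood density (g cm^-3): dry mass over fresh volume."""
    return sample.dry_mass_g / sample_volume(sample)


@dataclass
class SpeciesDensityTable:
    """Species -> (mean SWD g cm^-3, n samples), with a genus/default fallback."""

    values: dict[str, tuple[float, int]] = field(default_factory=dict)
    default_swd: float | None = None

    def validate(self) -> list[str]:
        out = []
        for sp, (swd, n) in self.values.items():
            if not 0 < swd < MAX_SWD:
                out.append(f"{sp}: SWD {swd} outside (0, {MAX_SWD})")
            if n < 1:
                out.append(f"{sp}: n must be >= 1")
        if self.default_swd is not None and not 0 < self.default_swd < MAX_SWD:
            out.append(f"default_swd {self.default_swd} outside (0, {MAX_SWD})")
        return out

    def lookup(self, species: str) -> tuple[float, str]:
        """Resolve SWD with provenance in {species, genus, default}."""
        return lookup_swd(species, self)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"species": sp, "swd_g_cm3": swd, "n_samples": n}
            for sp, (swd, n) in sorted(self.values.items())
        ]
        return pd.DataFrame(rows, columns=["species", "swd_g_cm3", "n_samples"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, default_swd: float | None = None):
        df = pd.read_csv(path, float_precision="round_trip")
        values = {
            str(r["species"]): (float(r["swd_g_cm3"]), int(r["n_samples"]))
            for _, r in df.iterrows()
        }
        return cls(values=values, default_swd=default_swd)


def species_mean_table(
    samples: Iterable[WoodSample], default_swd: float | None = None
) -> SpeciesDensityTable:
    """Average per-sample SWD within each species."""
    by_species: dict[str, list[float]] = {}
    for s in samples:
        by_species.setdefault(s.species, []).append(compute_swd(s))
    if not by_species:
        raise ValidationError("species_mean_table needs at least one sample")
    values = {
        sp: (sum(v) / len(v), len(v)) for sp, v in by_species.items()
    }
    return SpeciesDensityTable(values=values, default_swd=default_swd)


def _genus(species: str) -> str:
    return species.strip().split()[0].lower() if species.strip() else ""


def lookup_swd(species: str, table: SpeciesDensityTable) -> tuple[float, str]:
    """Resolve SWD for a species with fallback chain species -> genus -> default.

    The genus fallback averages the table entries sharing the species
    label's first (binomial genus) token.
    """
    if species in table.values:
        return table.values[species][0], "species"
    genus = _genus(species)
    if genus:
        matches = [swd for sp, (swd, _) in table.values.items() if _genus(sp) == genus]
        if matches:
            return sum(matches) / len(matches), "genus"
    if table.default_swd is not None:
        return table.default_swd, "default"
    raise SwdLookupError(
        f"no SWD for species {species!r}: not in table, no genus match, no default"
    )


def read_wood_samples(path: str | Path) -> list[WoodSample]:
    """Read the wood-sample CSV: species, sample_id, length_cm, d1..d5_cm, dry_mass_g."""
    df = pd.read_csv(path, float_precision="round_trip")
    samples = []
    for _, r in df.iterrows():
        samples.append(WoodSample(
            species=str(r["species"]),
            sample_id=str(r["sample_id"]),
            length_cm=float(r["length_cm"]),
            diameters_cm=tuple(float(r[f"d{i}_cm"]) for i in range(1, 6)),
            dry_mass_g=float(r["dry_mass_g"]),
        ))
    return samples


def write_wood_samples(samples: Iterable[WoodSample], path: str | Path) -> None:
    rows = []
    for s in samples:
        row = {"species": s.species, "sample_id": s.sample_id, "length_cm": s.length_cm}
        for i, d in enumerate(s.diameters_cm, start=1):
            row[f"d{i}_cm"] = d
        row["dry_mass_g"] = s.dry_mass_g
        rows.append(row)
    cols = ["species", "sample_id", "length_cm"] + [f"d{i}_cm" for i in range(1, 6)] + ["dry_mass_g"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.17g")
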