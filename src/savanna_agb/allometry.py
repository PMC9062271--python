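"""Allometric models and proxy-reconstruction formulas.

Two published generic models estimate individual aboveground biomass (AGB,
kg): a canopy-based model for shrub-like growth, driven by mean crown
diameter (m) and height (cm), and a stem-based model for tree-like growth,
driven by specific wood density (g cm^-3), DBH (cm) and height (m). Note
the deliberate unit asymmetry in height between the two models — callers
holding heights in cm must divide by 100 before calling :func:`stem_agb`;
the parameter name ``h_m`` enforces the contract.

Three locally calibrated regressions reconstruct missing proxies on damaged
or dead stems: pre-disturbance height from DBH (log-log power law), DBH
from basal diameter (proportionality), and basal circumference from a
circumference taken at an alternative height along the stem (linear taper).
Their coefficients live in a calibration model object exposing attributes
``a, b, s, t``; printed defaults are available when no local reference
trees exist.
"""

from __future__ import annotations

import math

from .exceptions import ConfigurationError, ValidationError


def canopy_agb(cd_m: float, h_cm: float) -> float:
    """Shrub/subadult AGB (kg) from mean crown diameter (m) and height (cm).

    AGB = exp(-0.370 + 1.903 ln CD + 0.652 ln h) * 1.403.  The output of
    this model reflects the *actual damaged state* of the canopy — it is a
    post-disturbance value.
    """
    if cd_m <= 0 or h_cm <= 0:
        raise ValidationError(f"canopy model needs CD > 0 and h > 0, got ({cd_m}, {h_cm})")
    return math.exp(-0.370 + 1.903 * math.log(cd_m) + 0.652 * math.log(h_cm)) * 1.403


def stem_agb(swd: float, dbh_cm: float, h_m: float) -> float:
    """Tree AGB (kg) from wood density (g cm^-3), DBH (cm) and height (m).

    AGB = 0.0673 * (SWD * DBH^2 * h)^0.976.  For a damaged tree this is the
    *pre-disturbance* value; recorded crown losses must be deducted to get
    standing AGB.
    """
    if swd <= 0 or dbh_cm <= 0 or h_m <= 0:
        raise ValidationError(
            f"stem model needs positive SWD, DBH, h; got ({swd}, {dbh_cm}, {h_m})"
        )
    return 0.0673 * (swd * dbh_cm ** 2 * h_m) ** 0.976


def height_from_dbh(dbh_cm: float, a: float, b: float) -> float:
    """Expected height (cm) at a given DBH under the power-law h = exp(a + b ln DBH)."""
    if dbh_cm <= 0:
        raise ValidationError(f"DBH must be > 0, got {dbh_cm}")
    return math.exp(a + b * math.log(dbh_cm))


def reconstruct_height(dbh_cm: float, h_obs_cm: float, model) -> float:
    """Pre-disturbance height (cm) for a damaged adult stem.

    The calibrated power law predicts the height the stem diameter would
    normally support; where the prediction falls below the observed height,
    the observed reading is kept (a tree is never shortened by correction).
    """
    if model is None:
        raise ConfigurationError("height reconstruction requires a calibration model")
    if h_obs_cm <= 0:
        raise ValidationError(f"observed height must be > 0, got {h_obs_cm}")
    return max(h_obs_cm, height_from_dbh(dbh_cm, model.a, model.b))


def dbh_from_basal(basal_circ_cm: float, model) -> float:
    """Surrogate DBH (cm) from basal circumference via DBH_est = s * basal_circ / pi."""
    if model is None:
        raise ConfigurationError("DBH reconstruction requires a calibration model")
    if basal_circ_cm <= 0:
        raise ValidationError(f"basal circumference must be > 0, got {basal_circ_cm}")
    return model.s * basal_circ_cm / math.pi


def basal_from_alternative(circ_hx_cm: float, hx_cm: float, model) -> float:
    """Basal circumference (cm) from a reading at height hx along the stem.

    basal = 130 * circ(hx) / (130 - t * hx); a linear taper anchored so that
    hx = 0 returns the reading unchanged.
    """
    if model is None:
        raise ConfigurationError("taper reconstruction requires a calibration model")
    if circ_hx_cm <= 0:
        raise ValidationError(f"circumference must be > 0, got {circ_hx_cm}")
    if hx_cm < 0:
        raise ValidationError(f"measurement height must be >= 0, got {hx_cm}")
    denom = 130.0 - model.t * hx_cm
    if denom <= 0:
        raise ValidationError(
            f"taper denominator non-positive at hx = {hx_cm} cm (t = {model.t}); "
            "reading taken too high along the stem"
        )
    return 130.0 * circ_hx_cm / denom
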