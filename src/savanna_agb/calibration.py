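"""Local calibration of the three proxy-reconstruction regressions.

The regressions are fitted on a healthy reference subset — adult non-gulliver
trees (class AA) with total recorded loss below the gulliver threshold and no
dead stems — because only their proxies still follow undisturbed allometric
relationships:

* height model:  h = exp(a + b * ln DBH), ordinary least squares on the log
  scale (R^2 reported on that scale);
* DBH model:     DBH = s * (basal_circumference / pi), least squares through
  the origin;
* taper model:   basal_circ = 130 * circ(hx) / (130 - t * hx), linearized to
  a one-parameter through-origin regression of 130 * (1 - circ(hx)/basal)
  on hx.

Each regression is a scikit-learn estimator (fit/predict, fitted attributes
with trailing underscores), so they compose with sklearn model-selection
tooling; :class:`CalibrationModels` bundles the fitted coefficients for the
estimation pipeline and can fall back to the printed reference coefficients
when no local reference trees are available.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import InsufficientDataError, SingularFitError
from .inventory import (
    DEFAULT_GULLIVER_LOSS_THRESHOLD,
    GrowthClass,
    WoodyIndividual,
)

#: Published reference coefficients, used when no local calibration exists.
PAPER_DEFAULT_COEFFICIENTS = {"a": 4.72595, "b": 0.63385, "s": 0.7968, "t": 0.2032}


def _column(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError(f"expected a single predictor column, got shape {x.shape}")
    return x


class HeightFromDbhRegression(BaseEstimator, RegressorMixin):
    """Power-law height-DBH model h = exp(a + b ln DBH), fit by log-log OLS.

    Fitted attributes: ``intercept_`` (a), ``slope_`` (b), ``rsquared_``
    (on the log scale), ``n_obs_``.
    """

    def fit(self, X, y):
        dbh, h = _column(X), np.asarray(y, dtype=float)
        if dbh.shape != h.shape:
            raise ValueError("X and y must have the same length")
        if len(dbh) < 3:
            raise InsufficientDataError(
                f"height model needs >= 3 (DBH, h) pairs, got {len(dbh)}"
            )
        if np.any(dbh <= 0) or np.any(h <= 0):
            raise ValueError("height model requires strictly positive DBH and h")
        lx, ly = np.log(dbh), np.log(h)
        if np.ptp(lx) == 0:
            raise SingularFitError("all DBH values identical; height fit is singular")
        res = sm.OLS(ly, sm.add_constant(lx)).fit()
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.rsquared_ = float(min(max(res.rsquared, 0.0), 1.0))
        self.n_obs_ = int(len(dbh))
        return self

    def predict(self, X):
        dbh = _column(X)
        return np.exp(self.intercept_ + self.slope_ * np.log(dbh))


class ProportionalRegression(BaseEstimator, RegressorMixin):
    """Least squares through the origin, y = slope * x.

    ``rsquared_`` is the uncentered R^2, the natural goodness-of-fit for a
    no-intercept model (always in [0, 1]).
    """

    def fit(self, X, y):
        x, yy = _column(X), np.asarray(y, dtype=float)
        if x.shape != yy.shape:
            raise ValueError("X and y must have the same length")
        if len(x) < 3:
            raise InsufficientDataError(
                f"through-origin fit needs >= 3 pairs, got {len(x)}"
            )
        sxx = float(np.dot(x, x))
        if sxx == 0:
            raise SingularFitError("predictor is identically zero; fit is singular")
        self.slope_ = float(np.dot(x, yy) / sxx)
        resid = yy - self.slope_ * x
        syy = float(np.dot(yy, yy))
        self.rsquared_ = 1.0 if syy == 0 else float(1.0 - np.dot(resid, resid) / syy)
        self.n_obs_ = int(len(x))
        return self

    def predict(self, X):
        return self.slope_ * _column(X)


class DbhFromBasalRegression(ProportionalRegression):
    """DBH = s * basal_diameter, with basal_diameter = basal_circumference / pi."""

    def fit(self, X, y):
        basal_circ = _column(X)
        if np.any(basal_circ <= 0):
            raise ValueError("basal circumferences must be > 0")
        return super().fit(basal_circ / math.pi, y)

    def predict(self, X):
        return super().predict(_column(X) / math.pi)


class TaperRegression(BaseEstimator, RegressorMixin):
    """Linear stem-taper coefficient t in basal = 130 * circ(hx) / (130 - t*hx).

    Fit on (circ_hx, hx, basal_circ) triples by regressing
    y = 130 * (1 - circ(hx)/basal_circ) on hx through the origin. ``predict``
    maps (circ_hx, hx) pairs to reconstructed basal circumferences.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("taper fit expects columns (circ_hx, hx, basal_circ)")
        circ, hx, basal = X[:, 0], X[:, 1], X[:, 2]
        if len(circ) < 3:
            raise InsufficientDataError(f"taper fit needs >= 3 tuples, got {len(circ)}")
        if np.any(circ <= 0) or np.any(basal <= 0) or np.any(hx < 0):
            raise ValueError("taper fit requires circ > 0, basal > 0, hx >= 0")
        if float(np.dot(hx, hx)) == 0:
            raise SingularFitError("all hx are zero; no taper information")
        yy = 130.0 * (1.0 - circ / basal)
        self.coef_ = float(np.dot(hx, yy) / np.dot(hx, hx))
        resid = yy - self.coef_ * hx
        syy = float(np.dot(yy, yy))
        self.rsquared_ = 1.0 if syy == 0 else float(1.0 - np.dot(resid, resid) / syy)
        self.n_obs_ = int(len(circ))
        bad = np.nonzero(130.0 - self.coef_ * hx <= 0)[0]
        self.excluded_ = bad.tolist()
        if bad.size:
            warnings.warn(
                f"{bad.size} taper tuples have non-positive denominators at the "
                f"fitted coefficient t = {self.coef_:.4f} (rows {bad.tolist()})"
            )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        circ, hx = X[:, 0], X[:, 1]
        denom = 130.0 - self.coef_ * hx
        if np.any(denom <= 0):
            raise ValueError("non-positive taper denominator for some hx")
        return 130.0 * circ / denom


# -- functional wrappers -----------------------------------------------------

def fit_height_model(pairs: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """OLS of ln h on ln DBH; returns (a, b, R^2 on the log scale)."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("height model needs >= 3 (DBH, h) pairs, got 0")
    m = HeightFromDbhRegression().fit(arr[:, 0], arr[:, 1])
    return m.intercept_, m.slope_, m.rsquared_


def fit_dbh_model(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Through-origin fit of DBH on basal diameter; returns (s, R^2)."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("DBH model needs >= 3 pairs, got 0")
    m = DbhFromBasalRegression().fit(arr[:, 0], arr[:, 1])
    return m.slope_, m.rsquared_


def fit_taper_model(
    tuples: Sequence[tuple[float, float, float]]
) -> tuple[float, float]:
    """Through-origin taper fit on (circ_hx, hx, basal) triples; returns (t, R^2)."""
    arr = np.asarray(list(tuples), dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("taper fit needs >= 3 tuples, got 0")
    m = TaperRegression().fit(arr)
    return m.coef_, m.rsquared_


# -- reference-subset selection ---------------------------------------------

@dataclass
class ReferenceStem:
    """One living stem of a healthy adult, with whatever proxies it carries."""

    individual_id: str
    dbh_cm: float | None        # measured, circ130 / pi
    basal_circ_cm: float | None
    height_cm: float
    alt_circ_cm: float | None
    alt_height_cm: float | None


def select_reference_subset(
    individuals: Iterable[WoodyIndividual],
    gulliver_loss_threshold: float = DEFAULT_GULLIVER_LOSS_THRESHOLD,
) -> list[ReferenceStem]:
    """Living stems of healthy adult non-gulliver trees, one entry per stem.

    Healthy means: growth class AA, total recorded loss below the gulliver
    threshold, and no dead stems — the subset whose proxies still reflect
    undisturbed allometry.
    """
    out = []
    for ind in individuals:
        if ind.growth_class != GrowthClass.AA:
            continue
        if ind.damage.total_percent >= gulliver_loss_threshold or ind.dead_stems():
            continue
        for s in ind.living_stems():
            dbh = s.circ130_cm / math.pi if s.circ130_cm is not None else None
            out.append(ReferenceStem(
                individual_id=ind.individual_id,
                dbh_cm=dbh,
                basal_circ_cm=s.basal_circ_cm,
                height_cm=ind.height_cm,
                alt_circ_cm=s.alt_circ_cm,
                alt_height_cm=s.alt_height_cm,
            ))
    return out


@dataclass
class CalibrationModels:
    """Fitted coefficients for the three reconstruction regressions.

    ``a, b``: height power law; ``s``: DBH proportionality; ``t``: taper.
    ``provenance`` is "local" for coefficients fitted from reference trees
    and "paper-default" for the printed reference values.
    """

    a: float
    b: float
    s: float
    t: float
    r2_height: float | None = None
    r2_dbh: float | None = None
    r2_taper: float | None = None
    n_height: int = 0
    n_dbh: int = 0
    n_taper: int = 0
    provenance: str = "local"

    @classmethod
    def paper_defaults(cls) -> "CalibrationModels":
        return cls(**PAPER_DEFAULT_COEFFICIENTS, provenance="paper-default")

    @classmethod
    def fit(
        cls,
        individuals: Iterable[WoodyIndividual],
        gulliver_loss_threshold: float = DEFAULT_GULLIVER_LOSS_THRESHOLD,
        require_taper: bool = False,
    ) -> "CalibrationModels":
        """Fit all three regressions from the healthy reference subset.

        The taper fit is optional by default: alternative-height readings are
        rare, and the printed taper coefficient is retained when fewer than
        three reference stems carry them (``require_taper=True`` raises
        instead).
        """
        stems = select_reference_subset(individuals, gulliver_loss_threshold)
        h_pairs = [(r.dbh_cm, r.height_cm) for r in stems if r.dbh_cm is not None]
        d_pairs = [
            (r.basal_circ_cm, r.dbh_cm)
            for r in stems
            if r.basal_circ_cm is not None and r.dbh_cm is not None
        ]
        t_tuples = [
            (r.alt_circ_cm, r.alt_height_cm, r.basal_circ_cm)
            for r in stems
            if r.alt_circ_cm is not None and r.basal_circ_cm is not None
        ]
        if len(h_pairs) < 3:
            raise InsufficientDataError(
                f"height fit: only {len(h_pairs)} usable reference stems (< 3)"
            )
        if len(d_pairs) < 3:
            raise InsufficientDataError(
                f"DBH fit: only {len(d_pairs)} usable reference stems (< 3)"
            )
        a, b, r2h = fit_height_model(h_pairs)
        s, r2d = fit_dbh_model(d_pairs)
        if len(t_tuples) >= 3:
            t, r2t = fit_taper_model(t_tuples)
            n_t = len(t_tuples)
        elif require_taper:
            raise InsufficientDataError(
                f"taper fit: only {len(t_tuples)} usable reference stems (< 3)"
            )
        else:
            t, r2t, n_t = PAPER_DEFAULT_COEFFICIENTS["t"], None, 0
        return cls(
            a=a, b=b, s=s, t=t,
            r2_height=r2h, r2_dbh=r2d, r2_taper=r2t,
            n_height=len(h_pairs), n_dbh=len(d_pairs), n_taper=n_t,
            provenance="local",
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModels":
        return cls(**json.loads(Path(path).read_text()))
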