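"""Bead calibration: from PE fluorescence to absolute receptor counts.

Quantibrite PE beads carry four known PE densities.  The log-log regression

    log10(geomean fluorescence per bead) = m * log10(PE per bead) + b

yields the instrument's slope/intercept; because the detection antibody is
PE-conjugated at a 1:1 ratio, inverting the fitted line converts any cell's
PE fluorescence directly into receptors per cell.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .errors import (
    CalibrationFailureError,
    DegenerateCurveError,
    InvalidArgumentError,
    InsufficientDataError,
)
from .events import EventTable

DEFAULT_NOMINAL_PE = (474.0, 5359.0, 23843.0, 62336.0)


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted log-log bead regression: slope ``m``, intercept ``b``."""

    m: float
    b: float
    r_squared: float
    level_geomeans: tuple[tuple[float, float], ...]  # (nominal_pe, geomean)

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise InvalidArgumentError("calibration slope must be > 0")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise InvalidArgumentError("r_squared must lie in [0, 1]")
        if len(self.level_geomeans) != 4:
            raise InvalidArgumentError("calibration requires exactly four bead levels")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "m": self.m,
                    "b": self.b,
                    "r_squared": self.r_squared,
                    "level_geomeans": [list(p) for p in self.level_geomeans],
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        d = json.loads(Path(path).read_text())
        return cls(
            d["m"], d["b"], d["r_squared"], tuple(tuple(p) for p in d["level_geomeans"])
        )


def cluster_bead_levels(
    bead_events: EventTable, nominal_pe: tuple[float, ...] = DEFAULT_NOMINAL_PE
) -> tuple[tuple[float, float], ...]:
    """Partition bead events into four intensity levels and take geomeans.

    One-dimensional k-means (k=4) on log10 fluorescence, initialized at the
    within-spread quantiles so the four clusters land on the four bead levels;
    clusters are sorted ascending and matched to the nominal densities
    ascending.  Returns ``((nominal, geomean), ...)``.
    """
    pe = bead_events.channel("ch_pe")
    pe = pe[pe > 0]
    if pe.size < 40:
        raise InsufficientDataError("need at least 40 positive bead events")
    x = np.log10(pe)

    init = np.quantile(x, [0.125, 0.375, 0.625, 0.875]).reshape(-1, 1)
    if np.unique(init).size < 4:
        raise CalibrationFailureError("bead intensities do not span four separable levels")
    km = KMeans(n_clusters=4, init=init, n_init=1, max_iter=300).fit(x.reshape(-1, 1))
    labels = km.labels_

    order = np.argsort(km.cluster_centers_.ravel())
    geomeans = []
    for cluster in order:
        members = x[labels == cluster]
        if members.size == 0:
            raise CalibrationFailureError("empty bead level cluster")
        geomeans.append(10.0 ** members.mean())
    if np.any(np.diff(geomeans) <= 0):
        raise CalibrationFailureError("bead level geomeans are not strictly increasing")
    return tuple(zip(sorted(nominal_pe), geomeans))


def fit_calibration(levels: tuple[tuple[float, float], ...]) -> CalibrationCurve:
    """Ordinary least squares of log10(geomean) on log10(nominal PE/bead)."""
    levels = tuple((float(n), float(g)) for n, g in levels)
    if len(levels) != 4 or len({n for n, _ in levels}) != 4:
        raise InvalidArgumentError("need four distinct bead levels")
    if any(n <= 0 or g <= 0 for n, g in levels):
        raise InvalidArgumentError("nominal values and geomeans must be positive")
    log_n = np.log10([n for n, _ in levels])
    log_g = np.log10([g for _, g in levels])
    fit = stats.linregress(log_n, log_g)
    return CalibrationCurve(
        m=float(fit.slope),
        b=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        level_geomeans=levels,
    )


def calibrate(bead_events: EventTable, nominal_pe: tuple[float, ...] = DEFAULT_NOMINAL_PE) -> CalibrationCurve:
    """Convenience: cluster bead levels then fit the calibration curve."""
    return fit_calibration(cluster_bead_levels(bead_events, nominal_pe))


def fluorescence_to_receptors(curve: CalibrationCurve, pe_values) -> np.ndarray:
    """Invert the calibration: receptors = 10**((log10(F) - b) / m).

    Non-positive fluorescence values map to 0 receptors (kept, not dropped,
    so event counts are preserved for downstream means).
    """
    if curve.m == 0:
        raise DegenerateCurveError("calibration slope is zero")
    v = np.asarray(pe_values, dtype=float)
    out = np.zeros_like(v)
    pos = v > 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # log10 of masked entries never used
        out[pos] = 10.0 ** ((np.log10(v[pos]) - curve.b) / curve.m)
    return out


def receptors_to_fluorescence(curve: CalibrationCurve, receptors) -> np.ndarray:
    """Forward model of the fitted curve (used in round-trip checks)."""
    r = np.asarray(receptors, dtype=float)
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = 10.0 ** (curve.m * np.log10(r[pos]) + curve.b)
    return out
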