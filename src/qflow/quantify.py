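"""Background subtraction, absolute receptor distributions, and pooling.

Order of operations is fixed: autofluorescence background is removed on the
*fluorescence* scale (weighted-mean ratio against the PE-FMO control), and
only then is fluorescence converted to receptors per cell through the bead
calibration.  Because the calibration is a power law with slope != 1 the
order is observable; this module implements fluorescence-first.

Per-subject distributions are summarized by median and interquartile range
(IQR) and flagged against the 500 receptors/cell specific-binding threshold:
sample medians below it are reported as little-to-no expression.  For group
pooling, every subject's dataset is resampled with replacement to a fixed
length (10,000 cPC cells / 1,000 cEC cells) so each subject contributes
equally to the pooled distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationCurve, fluorescence_to_receptors
from .errors import InsufficientCellsError, InvalidArgumentError
from .events import EventTable

DETECTION_THRESHOLD = 500.0  # receptors/cell; medians below = little-to-no expression
POOL_LENGTHS = {"cpc": 10_000, "cec": 1_000}
RESAMPLE_DRIFT_TOLERANCE = 0.02


@dataclass
class ReceptorDistribution:
    """Per-subject, per-cell-type absolute receptor counts."""

    subject_id: str
    cell_type: str  # cpc | cec
    receptor: str  # vegfr1 | vegfr2
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size < 1:
            raise InvalidArgumentError("distribution requires at least one cell")
        if np.any(self.counts < 0):
            raise InvalidArgumentError("receptor counts must be non-negative")

    @property
    def median(self) -> float:
        return float(np.percentile(self.counts, 50))

    @property
    def iqr(self) -> float:
        q25, q75 = np.percentile(self.counts, [25, 75])
        return float(q75 - q25)

    @property
    def below_threshold(self) -> bool:
        return self.median < DETECTION_THRESHOLD


@dataclass
class PooledDistribution:
    """Fixed-length equal-contribution pool of subject distributions."""

    group: str
    cell_type: str
    receptor: str
    counts: np.ndarray = field(repr=False)
    member_subjects: list[str] = field(default_factory=list)
    seed: int = 0

    @property
    def median(self) -> float:
        return float(np.percentile(self.counts, 50))

    @property
    def iqr(self) -> float:
        q25, q75 = np.percentile(self.counts, [25, 75])
        return float(q75 - q25)


def subtract_background(stained_pe, fmo_pe) -> np.ndarray:
    """Weighted-integral background subtraction on the fluorescence scale.

    Each stained value is scaled by ``1 - mean(fmo) / mean(stained)``.  A
    non-positive factor (background at or above the stained signal) clamps
    every output to zero with a warning: receptor counts are physically
    non-negative and such samples carry little-to-no expression.
    """
    stained = np.asarray(stained_pe, dtype=float)
    fmo = np.asarray(fmo_pe, dtype=float)
    if stained.size == 0 or fmo.size == 0:
        raise InvalidArgumentError("stained and FMO sequences must be non-empty")
    stained_mean = stained.mean()
    if stained_mean == 0:
        warnings.warn("stained mean fluorescence is zero; returning zeros", stacklevel=2)
        return np.zeros_like(stained)
    factor = 1.0 - fmo.mean() / stained_mean
    if factor < 0:
        warnings.warn(
            "background exceeds stained signal; clamping corrected values to zero",
            stacklevel=2,
        )
        return np.zeros_like(stained)
    return stained * factor


def build_distribution(
    gated_events: EventTable,
    curve: CalibrationCurve,
    fmo_events: EventTable,
    cell_type: str,
    receptor: str,
    subject_id: str = "",
) -> ReceptorDistribution:
    """Subtract background, convert to receptors/cell, and summarize.

    ``gated_events`` must already be restricted to the target cell class;
    ``fmo_events`` should be the PE-FMO tube gated to the same class so the
    background estimate comes from comparable cells.
    """
    if len(gated_events) == 0:
        raise InsufficientCellsError(subject_id)
    corrected = subtract_background(
        gated_events.channel("ch_pe"), fmo_events.channel("ch_pe")
    )
    counts = fluorescence_to_receptors(curve, corrected)
    return ReceptorDistribution(subject_id, cell_type, receptor, counts)


def resample_fixed_length(
    counts: np.ndarray, length: int, rng: np.random.Generator
) -> np.ndarray:
    """Resample a dataset with replacement to a fixed length.

    With-replacement sampling handles subjects with fewer cells than the
    target (rare cECs).  The resample should leave the median and IQR nearly
    unchanged; drift beyond 2% is reported as a warning, which can occur
    legitimately for very small source datasets.
    """
    resampled = rng.choice(counts, size=length, replace=True)
    for name, stat in (("median", lambda a: np.percentile(a, 50)),
                       ("IQR", lambda a: np.percentile(a, 75) - np.percentile(a, 25))):
        before, after = float(stat(counts)), float(stat(resampled))
        if before > 0 and abs(after - before) / before > RESAMPLE_DRIFT_TOLERANCE:
            warnings.warn(
                f"fixed-length resample shifted the {name} by "
                f"{abs(after - before) / before:.1%}",
                stacklevel=2,
            )
    return resampled


def pool_group(
    distributions: list[ReceptorDistribution], group: str, seed: int
) -> PooledDistribution:
    """Pool subject distributions at equal fixed length per subject."""
    if not distributions:
        raise InvalidArgumentError("cannot pool an empty membership")
    cell_types = {d.cell_type for d in distributions}
    receptors = {d.receptor for d in distributions}
    if len(cell_types) != 1 or len(receptors) != 1:
        raise InvalidArgumentError("pool members must share cell_type and receptor")
    cell_type, receptor = cell_types.pop(), receptors.pop()
    length = POOL_LENGTHS[cell_type]

    children = np.random.SeedSequence(seed).spawn(len(distributions))
    pooled = np.concatenate(
        [
            resample_fixed_length(d.counts, length, np.random.default_rng(child))
            for d, child in zip(distributions, children)
        ]
    )
    return PooledDistribution(
        group=group,
        cell_type=cell_type,
        receptor=receptor,
        counts=pooled,
        member_subjects=[d.subject_id for d in distributions],
        seed=seed,
    )
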