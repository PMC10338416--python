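"""Hierarchical gating with FMO-derived positive boundaries.

The gate hierarchy mirrors standard rare-event practice for CD34-enriched
blood samples:

    size (exclude debris/platelets <= 6 um)
    -> singlet (exclude width-inflated aggregates)
    -> viability (exclude dye-bright dead cells)
    -> CD34+CD31+          (circulating progenitor cells, cPCs)
    -> additionally CD146+ (circulating endothelial cells, cECs)

All gates are 1-D thresholds.  Positive boundaries for CD31, CD146 and
viability come from the matching fluorescence-minus-one (FMO) control tube at
a high percentile (default 99.5%); the size cutoff is anchored on the 6 um
PE calibration beads; the singlet cutoff is a width percentile of the
post-size population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, SchemaError
from .events import EventTable

DEFAULT_FMO_PERCENTILE = 0.995
DEFAULT_CD34_CUTOFF = 500.0  # fixed low cutoff above autofluorescence (pre-enriched tubes)
SINGLET_WIDTH_PERCENTILE = 0.98
BEAD_SIZE_PERCENTILE = 0.01

#: Stage names in gating order.
STAGES = ("total", "post_size", "post_singlet", "viable", "cpc", "cec")


@dataclass(frozen=True)
class GateBoundary:
    """A 1-D threshold on one channel, with provenance of how it was set."""

    channel: str
    cutoff: float
    source: str  # fmo_percentile | size_reference | width_reference | fixed

    def __post_init__(self) -> None:
        if not np.isfinite(self.cutoff):
            raise SchemaError("gate cutoff must be finite")


@dataclass
class GateResult:
    """Per-stage event masks and counts for one tube."""

    masks: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {stage: int(self.masks[stage].sum()) for stage in STAGES}

    @property
    def cec_fraction_of_cpc(self) -> float | None:
        """cEC share of gated cPC-lineage events; None when no cPCs gated."""
        cpc = int(self.masks["cpc"].sum())
        if cpc == 0:
            return None
        return int(self.masks["cec"].sum()) / cpc


def derive_fmo_boundary(
    fmo_events: EventTable, channel: str, percentile: float = DEFAULT_FMO_PERCENTILE
) -> GateBoundary:
    """Set a positive boundary at an upper percentile of the FMO channel."""
    values = fmo_events.channel(channel)
    if values.size == 0:
        raise InsufficientDataError(f"empty FMO table for channel {channel!r}")
    cutoff = float(np.quantile(values, percentile))
    return GateBoundary(channel=channel, cutoff=cutoff, source="fmo_percentile")


def derive_size_cutoff(
    bead_events: EventTable, percentile: float = BEAD_SIZE_PERCENTILE
) -> GateBoundary:
    """6 um size reference: a low percentile of bead forward scatter."""
    fsc = bead_events.channel("fsc_area")
    if fsc.size == 0:
        raise InsufficientDataError("empty bead table")
    return GateBoundary("fsc_area", float(np.quantile(fsc, percentile)), "size_reference")


def derive_width_cutoff(
    events: EventTable,
    size_cutoff: float,
    percentile: float = SINGLET_WIDTH_PERCENTILE,
) -> GateBoundary:
    """Singlet boundary: width percentile of the post-size population."""
    fsc = events.channel("fsc_area")
    width = events.channel("fsc_width")[fsc >= size_cutoff]
    if width.size == 0:
        raise InsufficientDataError("no events pass the size gate")
    return GateBoundary("fsc_width", float(np.quantile(width, percentile)), "width_reference")


def apply_gate_hierarchy(
    events: EventTable,
    boundaries: dict[str, GateBoundary],
    size_cutoff: float,
    width_cutoff: float | None = None,
) -> GateResult:
    """Run the fixed-order hierarchy on one tube and return per-stage masks.

    ``boundaries`` must provide ``cd31``, ``cd146`` and ``viability`` entries
    (FMO-derived) and may provide ``cd34`` (defaults to a fixed low cutoff).
    ``width_cutoff`` defaults to the 98th width percentile of the post-size
    events of this tube.  Each stage mask is the conjunction of all earlier
    stages, so later gates are always subsets of earlier ones.
    """
    for key in ("cd31", "cd146", "viability"):
        if key not in boundaries:
            raise SchemaError(f"missing required boundary {key!r}")
    cd34_cut = boundaries.get(
        "cd34", GateBoundary("ch_cd34", DEFAULT_CD34_CUTOFF, "fixed")
    ).cutoff

    fsc = events.channel("fsc_area")
    width = events.channel("fsc_width")
    if width_cutoff is None:
        post = width[fsc >= size_cutoff]
        width_cutoff = float(np.quantile(post, SINGLET_WIDTH_PERCENTILE)) if post.size else np.inf

    total = np.ones(len(events), dtype=bool)
    post_size = total & (fsc >= size_cutoff)
    post_singlet = post_size & (width <= width_cutoff)
    viable = post_singlet & (events.channel("ch_viability") <= boundaries["viability"].cutoff)
    cpc = (
        viable
        & (events.channel("ch_cd34") > cd34_cut)
        & (events.channel("ch_cd31") > boundaries["cd31"].cutoff)
    )
    cec = cpc & (events.channel("ch_cd146") > boundaries["cd146"].cutoff)

    return GateResult(
        masks={
            "total": total,
            "post_size": post_size,
            "post_singlet": post_singlet,
            "viable": viable,
            "cpc": cpc,
            "cec": cec,
        }
    )


def derive_subject_boundaries(
    tubes: dict[str, EventTable],
    percentile: float = DEFAULT_FMO_PERCENTILE,
    cd34_cutoff: float = DEFAULT_CD34_CUTOFF,
) -> dict[str, GateBoundary]:
    """Derive all positive boundaries from a subject's FMO tubes."""
    return {
        "cd31": derive_fmo_boundary(tubes["fmo_cd31"], "ch_cd31", percentile),
        "cd146": derive_fmo_boundary(tubes["fmo_cd146"], "ch_cd146", percentile),
        "viability": derive_fmo_boundary(tubes["fmo_viability"], "ch_viability", percentile),
        "cd34": GateBoundary("ch_cd34", cd34_cutoff, "fixed"),
    }
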