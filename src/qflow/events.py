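"""Per-event cytometry tables.

An :class:`EventTable` is a thin wrapper around a :class:`pandas.DataFrame`
holding one row per recorded event, with light-scatter and fluorescence
channels in arbitrary instrument units, plus the role of the tube it was
acquired from.  Synthetic tables additionally carry a ground-truth sidecar
frame (cell class, true receptor count, subpopulation index) keyed by event
index; real acquisitions have ``truth=None``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

#: Scatter and fluorescence channels every event table must provide.
CHANNELS = (
    "fsc_area",
    "fsc_width",
    "ssc",
    "ch_cd34",
    "ch_cd31",
    "ch_cd146",
    "ch_pe",
    "ch_viability",
)

#: Recognised tube roles.  ``fmo_viability`` is the viability-dye FMO used to
#: place the live/dead boundary; the remaining FMO tubes each omit exactly one
#: marker stain.
TUBE_ROLES = (
    "stained_v1",
    "stained_v2",
    "fmo_pe",
    "fmo_cd31",
    "fmo_cd146",
    "fmo_viability",
    "beads",
)

TRUTH_COLUMNS = (
    "is_cec",
    "is_cpc",
    "is_debris",
    "is_doublet",
    "is_dead",
    "subpop_index",
    "receptor_true",
)


@dataclass
class EventTable:
    """One acquisition tube: per-event channel values plus optional truth."""

    data: pd.DataFrame
    tube_role: str
    truth: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.tube_role not in TUBE_ROLES:
            raise SchemaError(f"unknown tube role {self.tube_role!r}")
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"event table missing channels: {missing}")
        vals = self.data[list(CHANNELS)].to_numpy()
        if not np.all(np.isfinite(vals)):
            raise SchemaError("non-finite channel values in event table")
        if self.truth is not None and len(self.truth) != len(self.data):
            raise SchemaError("truth sidecar length does not match events")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return len(self.data)

    def channel(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise SchemaError(f"channel {name!r} not present")
        return self.data[name].to_numpy()

    def subset(self, mask: np.ndarray) -> "EventTable":
        """Return a copy restricted to ``mask`` (boolean per event)."""
        truth = self.truth.loc[mask].reset_index(drop=True) if self.truth is not None else None
        return EventTable(
            self.data.loc[mask].reset_index(drop=True), self.tube_role, truth
        )

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path, truth_path: str | Path | None = None) -> None:
        """Write events as CSV (one row per event, documented header).

        Ground-truth labels, when present, go to a sidecar CSV keyed by the
        event index.
        """
        path = Path(path)
        df = self.data.copy()
        df.insert(0, "tube_role", self.tube_role)
        df.to_csv(path, index_label="event_index")
        if self.truth is not None:
            if truth_path is None:
                truth_path = path.with_suffix(".truth.csv")
            self.truth.to_csv(truth_path, index_label="event_index")

    @classmethod
    def from_csv(
        cls, path: str | Path, truth_path: str | Path | None = None
    ) -> "EventTable":
        df = pd.read_csv(path, index_col="event_index")
        role = str(df.pop("tube_role").iloc[0])
        truth = None
        if truth_path is not None and Path(truth_path).exists():
            truth = pd.read_csv(truth_path, index_col="event_index")
        return cls(df.reset_index(drop=True), role, truth)


def write_manifest(path: str | Path, manifest: dict) -> None:
    """Write a cohort manifest (subjects, tube files, seeds) as JSON."""
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
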