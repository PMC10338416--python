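"""End-to-end orchestration: cohort -> gates -> calibration -> distributions.

These helpers wire the stage modules together the way the assay is actually
run: one bead calibration per instrument run, per-subject FMO boundaries,
identical gating of stained and PE-FMO tubes (so the background estimate
comes from the same cell class), background subtraction on fluorescence, and
conversion to absolute receptor counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationCurve, calibrate
from .errors import InsufficientCellsError
from .gating import (
    DEFAULT_CD34_CUTOFF,
    DEFAULT_FMO_PERCENTILE,
    GateBoundary,
    GateResult,
    apply_gate_hierarchy,
    derive_size_cutoff,
    derive_subject_boundaries,
)
from .quantify import PooledDistribution, ReceptorDistribution, build_distribution, pool_group
from .synthdata import Cohort, CohortSubject

_RECEPTOR_TUBE = {"vegfr1": "stained_v1", "vegfr2": "stained_v2"}


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    boundaries: dict[str, GateBoundary]
    gates: dict[str, GateResult] = field(repr=False, default_factory=dict)
    distributions: dict[tuple[str, str], ReceptorDistribution] = field(
        repr=False, default_factory=dict
    )

    @property
    def cec_fraction_of_cpc(self) -> float | None:
        return self.gates["stained_v1"].cec_fraction_of_cpc


@dataclass
class CohortResult:
    curve: CalibrationCurve
    subjects: list[SubjectResult]

    def group_distributions(
        self, groups: str | list[str], cell_type: str, receptor: str
    ) -> list[ReceptorDistribution]:
        if isinstance(groups, str):
            groups = [groups]
        return [
            s.distributions[(cell_type, receptor)]
            for s in self.subjects
            if s.group in groups and (cell_type, receptor) in s.distributions
        ]

    def mean_cec_fraction(self) -> float:
        fractions = [
            s.cec_fraction_of_cpc for s in self.subjects if s.cec_fraction_of_cpc is not None
        ]
        return float(np.mean(fractions))


def process_subject(
    subject: CohortSubject,
    curve: CalibrationCurve,
    size_cutoff: float,
    fmo_percentile: float = DEFAULT_FMO_PERCENTILE,
    cd34_cutoff: float = DEFAULT_CD34_CUTOFF,
) -> SubjectResult:
    """Gate one subject's tubes and build their four receptor distributions."""
    tubes = subject.tubes
    boundaries = derive_subject_boundaries(tubes, fmo_percentile, cd34_cutoff)

    gates = {
        role: apply_gate_hierarchy(tubes[role], boundaries, size_cutoff)
        for role in ("stained_v1", "stained_v2", "fmo_pe")
    }

    result = SubjectResult(
        subject_id=subject.profile.subject_id,
        group=subject.profile.group,
        boundaries=boundaries,
        gates=gates,
    )
    fmo_tube = tubes["fmo_pe"]
    fmo_gate = gates["fmo_pe"]

    def quant_mask(gate: GateResult, cell_type: str) -> np.ndarray:
        # cPC distributions use CD146- progenitors only: the rare but very
        # bright cEC tail would otherwise inflate the stained-tube mean that
        # the background-correction ratio divides by.
        if cell_type == "cpc":
            return gate.masks["cpc"] & ~gate.masks["cec"]
        return gate.masks["cec"]

    for receptor, role in _RECEPTOR_TUBE.items():
        for cell_type in ("cpc", "cec"):
            stained_mask = quant_mask(gates[role], cell_type)
            fmo_mask = quant_mask(fmo_gate, cell_type)
            if not stained_mask.any() or not fmo_mask.any():
                continue  # recorded as absent; rare-cell dropout
            try:
                dist = build_distribution(
                    tubes[role].subset(stained_mask),
                    curve,
                    fmo_tube.subset(fmo_mask),
                    cell_type,
                    receptor,
                    subject_id=subject.profile.subject_id,
                )
            except InsufficientCellsError:
                continue
            result.distributions[(cell_type, receptor)] = dist
    return result


def analyze_cohort(
    cohort: Cohort,
    fmo_percentile: float = DEFAULT_FMO_PERCENTILE,
    cd34_cutoff: float = DEFAULT_CD34_CUTOFF,
) -> CohortResult:
    """Calibrate once per run, then process every subject."""
    curve = calibrate(cohort.bead_tube, cohort.instrument.nominal_pe_per_bead)
    size_cutoff = derive_size_cutoff(cohort.bead_tube).cutoff
    subjects = [
        process_subject(s, curve, size_cutoff, fmo_percentile, cd34_cutoff)
        for s in cohort.subjects
    ]
    return CohortResult(curve=curve, subjects=subjects)


def pooled_distribution(
    result: CohortResult,
    groups: str | list[str],
    cell_type: str,
    receptor: str,
    seed: int,
    label: str | None = None,
) -> PooledDistribution:
    """Pool one cell type x receptor across one or more groups."""
    dists = result.group_distributions(groups, cell_type, receptor)
    if label is None:
        label = groups if isinstance(groups, str) else "+".join(groups)
    return pool_group(dists, label, seed)
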