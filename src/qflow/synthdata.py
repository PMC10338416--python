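"""Synthetic cohort generator for quantitative flow cytometry (qFlow).

Real blood acquisitions for this assay are per-subject tube sets: two
receptor-stained tubes (VEGFR1-PE and VEGFR2-PE on CD34-enriched cells),
fluorescence-minus-one (FMO) controls for the PE, CD31, CD146 and viability
channels, and a four-level Quantibrite PE bead tube per instrument run.  This
module emulates all of them with known ground truth so the downstream stages
(gating, calibration, background subtraction, pooling, mixture decomposition,
group statistics) can be exercised and validated end-to-end.

The generative model, briefly:

* **Instrument.** PE fluorescence responds to the number of PE molecules on an
  event as a power law, ``F = 10^(m*log10(x) + b)`` — the same log-log
  linearity the bead calibration assumes.  Beads carry the four nominal PE
  densities (474 / 5,359 / 23,843 / 62,336 PE per bead) with configurable
  coefficient of variation.
* **Cells.** Each tube mixes circulating progenitor cells (cPCs,
  CD34+CD31+), a rare (~1%) circulating endothelial cell (cEC,
  additionally CD146+) subpopulation, plus debris, doublets and dead cells.
  Per-cell receptor numbers are drawn from group-specific log-normal mixtures;
  autofluorescence adds on the PE-molecule-equivalent scale before the
  instrument response, so FMO-based background subtraction is meaningful.
* **Contamination.** Debris sits below the 6 um bead size reference; doublets
  have inflated FSC width; dead cells are viability-dye bright.  Dead cells
  and debris are strongly autofluorescent in every channel (a standard
  cytometry artifact), which makes FMO-derived boundaries conservative.
* **Cohort.** Subjects are drawn per sex-by-age group with the study's
  demographic composition.  Between-subject biological variability shifts each
  subject's subpopulation medians and (for cECs) subpopulation weights; the
  shifts are drawn as mirrored, sum-to-zero sets within each group, so the
  realized group-level pooled parameters equal the configured conditions
  exactly (conditioned simulation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .events import EventTable

# --------------------------------------------------------------------------
# groups and demographic constants

GROUPS = ("female_pre", "female_post", "male_under50", "male_over50")

#: Default subjects per group: 23 total (11 females, 12 age-matched males).
DEFAULT_COHORT_COUNTS = {
    "female_pre": 5,
    "female_post": 6,
    "male_under50": 6,
    "male_over50": 6,
}

RACES = ("black", "white", "hispanic")
RACE_PROPORTIONS = (0.522, 0.261, 0.217)

AGE_BOUNDS = {"under50": (25, 49), "over50": (50, 60)}

# --------------------------------------------------------------------------
# instrument / staining constants (arbitrary units)

CELL_FSC_MEDIAN = 120.0
CELL_FSC_LOG10_SD = 0.06
DEBRIS_FSC_RANGE = (5.0, 45.0)
DOUBLET_FSC_FACTOR = 1.9

SINGLET_WIDTH_MEAN = 100.0
SINGLET_WIDTH_SD = 4.0
DOUBLET_WIDTH_FACTOR = 1.85

STAIN_POS_MEDIAN = 10_000.0  # marker-positive stain signal
STAIN_POS_LOG10_SD = 0.2
DEAD_AUTOFLUOR_FACTOR = 20.0  # dead/debris autofluorescence inflation
VIABILITY_DYE_MEDIAN = 50_000.0
VIABILITY_DYE_LOG10_SD = 0.2
PE_MEASUREMENT_LOG10_SD = 0.02

#: Between-subject sd of log10 subpopulation medians, per cell type.
SUBJECT_MEDIAN_LOG10_SD = {"cpc": 0.35, "cec": 0.05}
#: Between-subject sd of the top cEC component weight.
SUBJECT_WEIGHT_SD = 0.05
#: Between-subject sd of log10 cEC fraction.
SUBJECT_CEC_FRACTION_LOG10_SD = 0.10


class Subpop(NamedTuple):
    """One log-normal receptor subpopulation: weight, median, log10 spread."""

    weight: float
    median: float  # receptors/cell
    log10_sd: float


@dataclass(frozen=True)
class InstrumentModel:
    """Power-law fluorescence response plus bead noise model.

    ``m_true``/``b_true`` are the true slope/intercept of the log-log
    response that the bead calibration estimates; ``bead_cv`` is the
    coefficient of variation of bead fluorescence around each level.
    """

    m_true: float = 0.95
    b_true: float = 0.10
    bead_cv: float = 0.06
    nominal_pe_per_bead: tuple[float, ...] = (474.0, 5359.0, 23843.0, 62336.0)
    bead_fsc_mean: float = 60.0  # the 6 um size reference
    bead_fsc_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.m_true <= 0:
            raise InvalidArgumentError("m_true must be > 0")
        nom = self.nominal_pe_per_bead
        if any(b <= a for a, b in zip(nom, nom[1:])):
            raise InvalidArgumentError("nominal PE/bead values must be strictly increasing")

    def response(self, x: np.ndarray) -> np.ndarray:
        """Fluorescence produced by ``x`` PE-molecule equivalents (x > 0)."""
        x = np.asarray(x, dtype=float)
        return 10.0 ** (self.m_true * np.log10(x) + self.b_true)


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    age: int
    sex: str  # female | male
    race: str  # black | white | hispanic | other
    menopausal: str  # pre_peri | meno_post | not_applicable

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise InvalidArgumentError(f"bad sex {self.sex!r}")
        if self.sex == "male" and self.menopausal != "not_applicable":
            raise InvalidArgumentError("males must have menopausal='not_applicable'")
        if self.sex == "female":
            expected = "meno_post" if self.age >= 50 else "pre_peri"
            if self.menopausal != expected:
                raise InvalidArgumentError(
                    f"female age {self.age} must have menopausal={expected!r}"
                )

    @property
    def age_category(self) -> str:
        return "over50" if self.age >= 50 else "under50"

    @property
    def group(self) -> str:
        return group_of(self.sex, self.age)


def group_of(sex: str, age: int) -> str:
    """Sex-by-age group, with the study's 50-year menopause cutoff."""
    if sex == "female":
        return "female_post" if age >= 50 else "female_pre"
    return "male_over50" if age >= 50 else "male_under50"


def make_profile(subject_id: str, age: int, sex: str, race: str = "black") -> SubjectProfile:
    """Build a profile with the menopausal field filled in by the cohort rule."""
    if sex == "male":
        meno = "not_applicable"
    else:
        meno = "meno_post" if age >= 50 else "pre_peri"
    return SubjectProfile(subject_id, age, sex, race, meno)


@dataclass(frozen=True)
class GroupConfig:
    """Ground-truth population structure for one sex-by-age group."""

    group: str
    cec_fraction: float
    subpops_v1_cec: tuple[Subpop, ...]
    subpops_v2_cec: tuple[Subpop, ...]
    subpops_v1_cpc: tuple[Subpop, ...]
    subpops_v2_cpc: tuple[Subpop, ...]
    debris_fraction: float = 0.10
    doublet_fraction: float = 0.02
    dead_fraction: float = 0.05
    autofluor_median: float = 10.0
    autofluor_log10_sd: float = 0.30

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InvalidArgumentError(f"unknown group {self.group!r}")
        for frac in (
            self.cec_fraction,
            self.debris_fraction,
            self.doublet_fraction,
            self.dead_fraction,
        ):
            if not (0.0 <= frac <= 1.0):
                raise InvalidArgumentError("fractions must lie in [0, 1]")
        if self.debris_fraction + self.doublet_fraction + self.dead_fraction >= 1.0:
            raise InvalidArgumentError("contamination fractions leave no room for cells")
        for name in ("subpops_v1_cec", "subpops_v2_cec", "subpops_v1_cpc", "subpops_v2_cpc"):
            subpops = getattr(self, name)
            total = sum(s.weight for s in subpops)
            if abs(total - 1.0) > 1e-9:
                raise InvalidArgumentError(f"{name} weights sum to {total}, not 1")
            if any(s.median <= 0 or s.log10_sd <= 0 for s in subpops):
                raise InvalidArgumentError(f"{name} medians and spreads must be > 0")

    def subpops(self, cell_type: str, receptor: str) -> tuple[Subpop, ...]:
        key = {"vegfr1": "v1", "vegfr2": "v2"}[receptor]
        return getattr(self, f"subpops_{key}_{cell_type}")


def default_group_configs() -> dict[str, GroupConfig]:
    """Study-condition defaults for the four sex-by-age groups.

    cEC subpopulation weights/medians and cPC medians follow the pooled
    group values of the source study; cPC VEGFR2 is set below the 200
    receptors/cell reporting floor everywhere.  The premenopausal cEC VEGFR1
    low-component median (not printed for the two-component decomposition) is
    set so the pooled premenopausal cEC VEGFR1 median lands near its reported
    25,000 receptors/cell.
    """
    sd_cec, sd_cpc = 0.35, 0.50

    def cpc(median: float) -> tuple[Subpop, ...]:
        return (Subpop(1.0, median, sd_cpc),)

    male_cec_v1 = (Subpop(0.731, 3100.0, sd_cec), Subpop(0.269, 206_000.0, sd_cec))
    male_cec_v2 = (Subpop(0.724, 3000.0, sd_cec), Subpop(0.276, 155_000.0, sd_cec))

    return {
        "female_post": GroupConfig(
            group="female_post",
            cec_fraction=0.0098,
            subpops_v1_cec=(Subpop(1.0, 2900.0, sd_cec),),
            subpops_v2_cec=(Subpop(1.0, 3400.0, sd_cec),),
            subpops_v1_cpc=cpc(650.0),
            subpops_v2_cpc=cpc(150.0),
        ),
        "female_pre": GroupConfig(
            group="female_pre",
            cec_fraction=0.0098,
            subpops_v1_cec=(Subpop(0.553, 8700.0, sd_cec), Subpop(0.447, 138_000.0, sd_cec)),
            subpops_v2_cec=(
                Subpop(0.558, 2600.0, sd_cec),
                Subpop(0.218, 39_100.0, sd_cec),
                Subpop(0.224, 236_000.0, sd_cec),
            ),
            subpops_v1_cpc=cpc(88.0),
            subpops_v2_cpc=cpc(150.0),
        ),
        "male_under50": GroupConfig(
            group="male_under50",
            cec_fraction=0.0098,
            subpops_v1_cec=male_cec_v1,
            subpops_v2_cec=male_cec_v2,
            subpops_v1_cpc=cpc(330.0),
            subpops_v2_cpc=cpc(150.0),
        ),
        "male_over50": GroupConfig(
            group="male_over50",
            cec_fraction=0.0098,
            subpops_v1_cec=male_cec_v1,
            subpops_v2_cec=male_cec_v2,
            subpops_v1_cpc=cpc(250.0),
            subpops_v2_cpc=cpc(150.0),
        ),
    }


# --------------------------------------------------------------------------
# bead tube


def generate_bead_tube(
    instrument: InstrumentModel, n_per_level: int, seed: int
) -> EventTable:
    """Simulate a four-level Quantibrite PE bead acquisition.

    Each level's fluorescence is log-normal around the instrument response to
    its nominal PE density, with coefficient of variation ``bead_cv``; the
    geometric mean of each level therefore equals the noiseless response.
    """
    if n_per_level <= 0:
        raise InvalidArgumentError("n_per_level must be positive")
    rng = np.random.default_rng(seed)
    sigma_log10 = math.sqrt(math.log(1.0 + instrument.bead_cv**2)) / math.log(10.0)

    frames, truth_levels = [], []
    for level, nominal in enumerate(instrument.nominal_pe_per_bead):
        center = instrument.m_true * math.log10(nominal) + instrument.b_true
        log10_pe = center + rng.normal(0.0, sigma_log10, n_per_level)
        frames.append(
            pd.DataFrame(
                {
                    "fsc_area": rng.normal(
                        instrument.bead_fsc_mean, instrument.bead_fsc_sd, n_per_level
                    ),
                    "fsc_width": rng.normal(SINGLET_WIDTH_MEAN, SINGLET_WIDTH_SD, n_per_level),
                    "ssc": 100.0 * 10 ** rng.normal(0.0, 0.05, n_per_level),
                    "ch_cd34": 10.0 * 10 ** rng.normal(0.0, 0.2, n_per_level),
                    "ch_cd31": 10.0 * 10 ** rng.normal(0.0, 0.2, n_per_level),
                    "ch_cd146": 10.0 * 10 ** rng.normal(0.0, 0.2, n_per_level),
                    "ch_pe": 10.0**log10_pe,
                    "ch_viability": 10.0 * 10 ** rng.normal(0.0, 0.2, n_per_level),
                }
            )
        )
        truth_levels.append(np.full(n_per_level, level))

    data = pd.concat(frames, ignore_index=True)
    n = len(data)
    truth = pd.DataFrame(
        {
            "is_cec": np.zeros(n, bool),
            "is_cpc": np.zeros(n, bool),
            "is_debris": np.zeros(n, bool),
            "is_doublet": np.zeros(n, bool),
            "is_dead": np.zeros(n, bool),
            "subpop_index": np.full(n, -1),
            "receptor_true": np.full(n, np.nan),
            "bead_level": np.concatenate(truth_levels),
        }
    )
    return EventTable(data, "beads", truth)


# --------------------------------------------------------------------------
# subject tubes

_STAINED_CHANNELS = {
    "stained_v1": {"pe", "cd31", "cd146", "viability"},
    "stained_v2": {"pe", "cd31", "cd146", "viability"},
    "fmo_pe": {"cd31", "cd146", "viability"},
    "fmo_cd31": {"pe", "cd146", "viability"},
    "fmo_cd146": {"pe", "cd31", "viability"},
    "fmo_viability": {"pe", "cd31", "cd146"},
}


def _draw_mixture(
    subpops: tuple[Subpop, ...], size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw receptor counts and component indices from a log-normal mixture."""
    weights = np.array([s.weight for s in subpops])
    comp = rng.choice(len(subpops), size=size, p=weights / weights.sum())
    medians = np.array([s.median for s in subpops])[comp]
    sds = np.array([s.log10_sd for s in subpops])[comp]
    values = medians * 10.0 ** rng.normal(0.0, sds)
    return values, comp


def _lognormal(rng: np.random.Generator, median: float, log10_sd: float, size: int) -> np.ndarray:
    return median * 10.0 ** rng.normal(0.0, log10_sd, size)


def generate_subject_tubes(
    profile: SubjectProfile,
    config: GroupConfig,
    instrument: InstrumentModel,
    n_events: int = 50_000,
    seed: int = 0,
) -> dict[str, EventTable]:
    """Simulate one subject's full tube set (stained + FMO controls).

    Returns a mapping from tube role to :class:`EventTable`, each with a
    ground-truth sidecar (event class, true receptor count, subpopulation
    index for that tube's receptor).
    """
    if config.group != profile.group:
        raise InvalidArgumentError(
            f"config group {config.group!r} does not match subject group {profile.group!r}"
        )
    if n_events < 1000:
        raise InvalidArgumentError("n_events must be at least 1000")

    children = np.random.SeedSequence(seed).spawn(len(_STAINED_CHANNELS))
    tubes: dict[str, EventTable] = {}
    for child, role in zip(children, _STAINED_CHANNELS):
        tubes[role] = _make_tube(role, config, instrument, n_events, np.random.default_rng(child))
    return tubes


def _make_tube(
    role: str,
    config: GroupConfig,
    instrument: InstrumentModel,
    n: int,
    rng: np.random.Generator,
) -> EventTable:
    stains = _STAINED_CHANNELS[role]
    receptor = "vegfr2" if role == "stained_v2" else "vegfr1"

    p_cell = 1.0 - config.debris_fraction - config.doublet_fraction - config.dead_fraction
    probs = [
        config.debris_fraction,
        config.doublet_fraction,
        config.dead_fraction,
        p_cell * (1.0 - config.cec_fraction),
        p_cell * config.cec_fraction,
    ]
    n_debris, n_doublet, n_dead, n_cpc, n_cec = rng.multinomial(n, probs)

    af_med, af_sd = config.autofluor_median, config.autofluor_log10_sd
    af_bright = af_med * DEAD_AUTOFLUOR_FACTOR

    blocks: list[pd.DataFrame] = []
    truths: list[pd.DataFrame] = []

    def live_marker(stained: bool, size: int, factor: float = 1.0) -> np.ndarray:
        if stained:
            return factor * _lognormal(rng, STAIN_POS_MEDIAN, STAIN_POS_LOG10_SD, size)
        return factor * _lognormal(rng, af_med, af_sd, size)

    def pe_channel(x: np.ndarray) -> np.ndarray:
        noise = 10.0 ** rng.normal(0.0, PE_MEASUREMENT_LOG10_SD, len(x))
        return instrument.response(x) * noise

    def add_block(size: int, cls: str) -> None:
        if size == 0:
            return
        is_cell = cls in ("cpc", "cec")
        receptor_true = np.full(size, np.nan)
        subpop_index = np.full(size, -1)

        # --- scatter
        if cls == "debris":
            fsc = rng.uniform(*DEBRIS_FSC_RANGE, size)
            width = rng.normal(SINGLET_WIDTH_MEAN, SINGLET_WIDTH_SD, size)
            ssc = _lognormal(rng, 30.0, 0.2, size)
        else:
            factor = DOUBLET_FSC_FACTOR if cls == "doublet" else 1.0
            fsc = factor * _lognormal(rng, CELL_FSC_MEDIAN, CELL_FSC_LOG10_SD, size)
            wmean = SINGLET_WIDTH_MEAN * (DOUBLET_WIDTH_FACTOR if cls == "doublet" else 1.0)
            wsd = SINGLET_WIDTH_SD * (DOUBLET_WIDTH_FACTOR if cls == "doublet" else 1.0)
            width = rng.normal(wmean, wsd, size)
            ssc = _lognormal(rng, 150.0, 0.10, size)

        # --- marker channels
        if cls in ("debris", "dead"):
            cd34 = _lognormal(rng, af_bright, af_sd, size)
            cd31 = _lognormal(rng, af_bright, af_sd, size)
            cd146 = _lognormal(rng, af_bright, af_sd, size)
        elif cls == "doublet":
            cd34 = live_marker(True, size) + live_marker(True, size)
            cd31 = live_marker("cd31" in stains, size) + live_marker("cd31" in stains, size)
            cd146 = 2.0 * _lognormal(rng, af_med, af_sd, size)
        else:
            cd34 = live_marker(True, size)
            cd31 = live_marker("cd31" in stains, size)
            cd146 = live_marker("cd146" in stains and cls == "cec", size)
            if cls == "cpc" and "cd146" not in stains:
                pass  # already background
        # --- viability channel
        if cls == "dead":
            if "viability" in stains:
                viability = _lognormal(rng, VIABILITY_DYE_MEDIAN, VIABILITY_DYE_LOG10_SD, size)
            else:
                viability = _lognormal(rng, af_bright, af_sd, size)
        elif cls == "debris":
            viability = _lognormal(rng, af_bright, af_sd, size)
        else:
            viability = _lognormal(rng, af_med, af_sd, size)
            if cls == "doublet":
                viability = viability + _lognormal(rng, af_med, af_sd, size)

        # --- PE channel: receptors + autofluorescence equivalents
        if cls in ("debris", "dead"):
            x = _lognormal(rng, af_bright, af_sd, size)
        elif cls == "doublet":
            x = _lognormal(rng, af_med, af_sd, size) + _lognormal(rng, af_med, af_sd, size)
            if "pe" in stains:
                r1, _ = _draw_mixture(config.subpops("cpc", receptor), size, rng)
                r2, _ = _draw_mixture(config.subpops("cpc", receptor), size, rng)
                x = x + r1 + r2
        else:
            x = _lognormal(rng, af_med, af_sd, size)
            if "pe" in stains:
                r, comp = _draw_mixture(config.subpops(cls, receptor), size, rng)
                x = x + r
                receptor_true = r
                subpop_index = comp

        blocks.append(
            pd.DataFrame(
                {
                    "fsc_area": fsc,
                    "fsc_width": width,
                    "ssc": ssc,
                    "ch_cd34": cd34,
                    "ch_cd31": cd31,
                    "ch_cd146": cd146,
                    "ch_pe": pe_channel(x),
                    "ch_viability": viability,
                }
            )
        )
        truths.append(
            pd.DataFrame(
                {
                    "is_cec": np.full(size, cls == "cec"),
                    "is_cpc": np.full(size, cls == "cpc"),
                    "is_debris": np.full(size, cls == "debris"),
                    "is_doublet": np.full(size, cls == "doublet"),
                    "is_dead": np.full(size, cls == "dead"),
                    "subpop_index": subpop_index,
                    "receptor_true": receptor_true,
                }
            )
        )

    add_block(n_debris, "debris")
    add_block(n_doublet, "doublet")
    add_block(n_dead, "dead")
    add_block(n_cpc, "cpc")
    add_block(n_cec, "cec")

    data = pd.concat(blocks, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    order = rng.permutation(len(data))
    return EventTable(
        data.iloc[order].reset_index(drop=True),
        role,
        truth.iloc[order].reset_index(drop=True),
    )


# --------------------------------------------------------------------------
# cohort


@dataclass
class CohortSubject:
    profile: SubjectProfile
    config: GroupConfig  # subject-adjusted copy of the group config
    tubes: dict[str, EventTable]


@dataclass
class Cohort:
    subjects: list[CohortSubject]
    bead_tube: EventTable
    instrument: InstrumentModel
    seed: int

    def by_group(self, group: str) -> list[CohortSubject]:
        return [s for s in self.subjects if s.profile.group == group]


def _mirrored(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Symmetric, exactly sum-to-zero draws: pairs (z, -z) plus a zero if odd."""
    half = n // 2
    base = rng.normal(0.0, sd, half)
    out = np.concatenate([base, -base, np.zeros(n - 2 * half)])
    return rng.permutation(out)


def _adjust_subpops(
    subpops: tuple[Subpop, ...], median_shift_log10: float, top_weight_shift: float
) -> tuple[Subpop, ...]:
    """Shift all component medians by 10**shift; move weight into the top component."""
    scaled = [
        Subpop(s.weight, s.median * 10.0**median_shift_log10, s.log10_sd) for s in subpops
    ]
    if len(scaled) > 1 and top_weight_shift != 0.0:
        w_top_old = scaled[-1].weight
        w_top = float(np.clip(w_top_old + top_weight_shift, 0.02, 0.95))
        rescale = (1.0 - w_top) / (1.0 - w_top_old)
        scaled = [Subpop(s.weight * rescale, s.median, s.log10_sd) for s in scaled[:-1]] + [
            Subpop(w_top, scaled[-1].median, scaled[-1].log10_sd)
        ]
        total = sum(s.weight for s in scaled)
        scaled = [Subpop(s.weight / total, s.median, s.log10_sd) for s in scaled]
    return tuple(scaled)


def generate_cohort(
    n_subjects_per_group: dict[str, int] | None = None,
    seed: int = 0,
    n_events: int = 50_000,
    n_beads_per_level: int = 5000,
    configs: dict[str, GroupConfig] | None = None,
    instrument: InstrumentModel | None = None,
) -> Cohort:
    """Generate a full synthetic cohort (default: 23 subjects) plus bead tube.

    Deterministic given ``seed``.  Subject-level biological variability
    (median shifts, cEC weight jitter, cEC-fraction jitter) is applied as
    mirrored within-group sets so every group's realized pooled structure
    matches its configured :class:`GroupConfig` exactly.
    """
    counts = dict(DEFAULT_COHORT_COUNTS if n_subjects_per_group is None else n_subjects_per_group)
    for group, count in counts.items():
        if group not in GROUPS:
            raise InvalidArgumentError(f"unknown group {group!r}")
        if count < 0:
            raise InvalidArgumentError("subject counts must be >= 0")
    configs = default_group_configs() if configs is None else configs
    instrument = InstrumentModel() if instrument is None else instrument

    master = np.random.default_rng(np.random.SeedSequence(seed))
    bead_tube = generate_bead_tube(
        instrument, n_beads_per_level, int(master.integers(2**31))
    )

    subjects: list[CohortSubject] = []
    for group in GROUPS:
        n_group = counts.get(group, 0)
        if n_group == 0:
            continue
        base = configs[group]
        age_lo, age_hi = AGE_BOUNDS["over50" if group.endswith(("post", "over50")) else "under50"]
        sex = "female" if group.startswith("female") else "male"

        # mirrored subject effects, one set per adjusted quantity
        median_shifts = {
            (ct, r): _mirrored(master, n_group, SUBJECT_MEDIAN_LOG10_SD[ct])
            for ct in ("cpc", "cec")
            for r in ("vegfr1", "vegfr2")
        }
        weight_shifts = {
            r: _mirrored(master, n_group, SUBJECT_WEIGHT_SD) for r in ("vegfr1", "vegfr2")
        }
        log_f = _mirrored(master, n_group, SUBJECT_CEC_FRACTION_LOG10_SD)
        f_factors = 10.0**log_f
        f_factors = f_factors / f_factors.mean()  # keep the group mean fraction exact

        for i in range(n_group):
            age = int(master.integers(age_lo, age_hi + 1))
            race = RACES[int(master.choice(len(RACES), p=RACE_PROPORTIONS))]
            profile = make_profile(f"{group}_{i + 1:02d}", age, sex, race)
            cfg = replace(
                base,
                cec_fraction=float(base.cec_fraction * f_factors[i]),
                subpops_v1_cpc=_adjust_subpops(
                    base.subpops_v1_cpc, median_shifts[("cpc", "vegfr1")][i], 0.0
                ),
                subpops_v2_cpc=_adjust_subpops(
                    base.subpops_v2_cpc, median_shifts[("cpc", "vegfr2")][i], 0.0
                ),
                subpops_v1_cec=_adjust_subpops(
                    base.subpops_v1_cec,
                    median_shifts[("cec", "vegfr1")][i],
                    weight_shifts["vegfr1"][i],
                ),
                subpops_v2_cec=_adjust_subpops(
                    base.subpops_v2_cec,
                    median_shifts[("cec", "vegfr2")][i],
                    weight_shifts["vegfr2"][i],
                ),
            )
            tube_seed = int(master.integers(2**31))
            tubes = generate_subject_tubes(profile, cfg, instrument, n_events, tube_seed)
            subjects.append(CohortSubject(profile, cfg, tubes))

    return Cohort(subjects, bead_tube, instrument, seed)
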