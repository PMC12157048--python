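"""Predictive body-composition equations and the measurement record they act on.

The package's core chain estimates whole-body fat mass percentage (FM%) three
ways for each participant:

* ``evans_fm_percent`` — the Evans 3-skinfold anthropometric equation
  (triceps + abdominal + thigh), with sex (0 = male, 1 = female) and race
  (0 = white, 1 = black) indicator terms;
* the same equation fed with ultrasound-derived skinfolds, i.e. the raw
  single-layer US thickness doubled (``double_us_thickness``);
* a modified four-component (4C) reference: Wang's 4C fat-mass equation over
  body volume (from DXA compartments), total body water (from single-frequency
  BIA resistance), bone mineral content and body mass.

All functions are pure and unrounded; rounding to 0.1 mm happens only where
measurements are *recorded* (cohort generation / input files), never inside an
equation. FM% outside [0, 100] is possible on extreme inputs and is flagged by
``estimate_all`` rather than clamped — a validation study needs to see
pathological outputs.

Note the sex-coding trap: the Evans equation codes female = 1 while the total
body water equation codes male = 1. ``ParticipantRecord`` stores both codings
and validates that they are inverses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .exceptions import InvalidInputError

SITES = ("triceps", "abdominal", "thigh")


# --------------------------------------------------------------------------- #
# Constants
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class EvansConstants:
    """Coefficients of the Evans 3-skinfold FM% equation."""

    intercept: float = 8.997
    skf_sum_coef: float = 0.24658
    sex_coef: float = 6.343   # subtracted for females (sex code 1)
    race_coef: float = 1.998  # subtracted for black participants (race code 1)


@dataclass(frozen=True)
class Wang4CConstants:
    """Coefficients of Wang's four-component fat-mass equation."""

    bv_coef: float = 2.748
    tbw_coef: float = 0.699
    bmc_coef: float = 1.129
    bm_coef: float = 2.051


@dataclass(frozen=True)
class BodyVolumeDensities:
    """Assumed compartment densities (kg/L) for the DXA body-volume equation."""

    fat: float = 0.9007
    lean_soft: float = 1.064
    bmc: float = 2.982


@dataclass(frozen=True)
class TBWConstants:
    """Coefficients of the BIA total-body-water equation (stature in cm,
    resistance in ohm, male = 1)."""

    intercept: float = 0.286
    impedance_coef: float = 0.195
    mass_coef: float = 0.385
    sex_coef: float = 5.086


@dataclass(frozen=True)
class EquationConstants:
    """Immutable bundle of every published coefficient used by the chain."""

    evans: EvansConstants = field(default_factory=EvansConstants)
    wang4c: Wang4CConstants = field(default_factory=Wang4CConstants)
    body_volume_densities: BodyVolumeDensities = field(
        default_factory=BodyVolumeDensities
    )
    tbw: TBWConstants = field(default_factory=TBWConstants)
    doubling_factor: float = 2.0


DEFAULT_CONSTANTS = EquationConstants()


# --------------------------------------------------------------------------- #
# Domain types
# --------------------------------------------------------------------------- #

def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise InvalidInputError(f"{field_name}: {message}")


def _check_sites(values: Mapping[str, float], field_name: str) -> dict[str, float]:
    if set(values) != set(SITES):
        raise InvalidInputError(
            f"{field_name}: expected exactly the sites {SITES}, got {sorted(values)}"
        )
    for site, v in values.items():
        _require(v > 0, f"{field_name}[{site}]", "must be strictly positive")
    return {site: float(values[site]) for site in SITES}


@dataclass
class ParticipantRecord:
    """One subject's raw measurements: anthropometry, US, DXA and BIA.

    ``sex_code_evans`` (0 = male, 1 = female) and ``sex_code_tbw``
    (1 = male, 0 = female) must sum to one; both are stored because the two
    equations use opposite codings.
    """

    id: str
    sex_code_evans: int
    sex_code_tbw: int
    body_mass: float            # kg
    stature: float              # cm
    skinfold_mm: Mapping[str, float]
    us_thickness_mm: Mapping[str, float]
    dxa_fat_pct: float          # percent of body mass
    lean_soft_mass: float       # kg
    bone_mineral_content: float  # kg
    resistance: float           # ohm at 50 kHz
    race_code: int = 0          # 0 = white, 1 = black

    def __post_init__(self) -> None:
        _require(self.sex_code_evans in (0, 1), "sex_code_evans", "must be 0 or 1")
        _require(self.sex_code_tbw in (0, 1), "sex_code_tbw", "must be 0 or 1")
        _require(
            self.sex_code_evans + self.sex_code_tbw == 1,
            "sex_code_evans/sex_code_tbw",
            "the two sex codings must be inverses (their sum must be 1)",
        )
        _require(self.race_code in (0, 1), "race_code", "must be 0 or 1")
        for name in ("body_mass", "stature", "lean_soft_mass",
                     "bone_mineral_content", "resistance"):
            _require(getattr(self, name) > 0, name, "must be strictly positive")
        _require(0 <= self.dxa_fat_pct <= 100, "dxa_fat_pct",
                 "must lie in [0, 100]")
        self.skinfold_mm = _check_sites(self.skinfold_mm, "skinfold_mm")
        self.us_thickness_mm = _check_sites(self.us_thickness_mm, "us_thickness_mm")

    @property
    def skinfold_sum(self) -> float:
        """Caliper triceps + abdominal + thigh sum (mm)."""
        return sum(self.skinfold_mm.values())

    @property
    def us_derived_skinfold_sum(self) -> float:
        """Sum of the doubled US thicknesses (mm)."""
        return sum(double_us_thickness(v) for v in self.us_thickness_mm.values())


@dataclass(frozen=True)
class FourComponentInputs:
    """The four ingredients of Wang's 4C equation."""

    body_volume: float          # L
    total_body_water: float     # kg (numerically treated as L at density 1)
    bone_mineral_content: float  # kg
    body_mass: float            # kg

    def __post_init__(self) -> None:
        for name in ("body_volume", "total_body_water",
                     "bone_mineral_content", "body_mass"):
            _require(getattr(self, name) > 0, name, "must be strictly positive")
        _require(self.total_body_water < self.body_mass,
                 "total_body_water", "must be smaller than body_mass")
        _require(self.bone_mineral_content < self.body_mass,
                 "bone_mineral_content", "must be smaller than body_mass")


@dataclass(frozen=True)
class FatMassEstimates:
    """Per-subject FM% under the three methods, with out-of-range flags."""

    id: str
    fm_pct_4c: float
    fm_pct_evans_anthro: float
    fm_pct_evans_us: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("fm_pct_4c", "fm_pct_evans_anthro", "fm_pct_evans_us"):
            _require(math.isfinite(getattr(self, name)), name, "must be finite")


# --------------------------------------------------------------------------- #
# Equations
# --------------------------------------------------------------------------- #

def evans_fm_percent(
    skf_sum: float,
    sex_code: int,
    race_code: int = 0,
    constants: EquationConstants = DEFAULT_CONSTANTS,
) -> float:
    """Evans FM% from a 3-skinfold sum (mm); sex 0 = male, race 0 = white."""
    _require(skf_sum >= 0, "skf_sum", "must be non-negative")
    _require(sex_code in (0, 1), "sex_code", "must be 0 or 1")
    _require(race_code in (0, 1), "race_code", "must be 0 or 1")
    c = constants.evans
    return (c.intercept + c.skf_sum_coef * skf_sum
            - c.sex_coef * sex_code - c.race_coef * race_code)


def double_us_thickness(
    us_thickness: float,
    constants: EquationConstants = DEFAULT_CONSTANTS,
) -> float:
    """Convert a raw single-layer US thickness (mm) to a US-derived skinfold."""
    _require(us_thickness >= 0, "us_thickness", "must be non-negative")
    return constants.doubling_factor * us_thickness


def wang_4c_fm_percent(
    inputs: FourComponentInputs,
    constants: EquationConstants = DEFAULT_CONSTANTS,
) -> float:
    """Wang's 4C FM% from body volume, water, bone mineral and body mass."""
    if inputs.body_mass <= 0:
        raise InvalidInputError("body_mass: must be strictly positive")
    c = constants.wang4c
    numerator = (c.bv_coef * inputs.body_volume
                 - c.tbw_coef * inputs.total_body_water
                 + c.bmc_coef * inputs.bone_mineral_content
                 - c.bm_coef * inputs.body_mass)
    return numerator / inputs.body_mass * 100.0


def dxa_body_volume(
    dxa_fat_pct: float,
    body_mass: float,
    lean_soft_mass: float,
    bone_mineral_content: float,
    constants: EquationConstants = DEFAULT_CONSTANTS,
) -> float:
    """Body volume (L) from DXA compartments at assumed densities."""
    for name, v in (("dxa_fat_pct", dxa_fat_pct), ("body_mass", body_mass),
                    ("lean_soft_mass", lean_soft_mass),
                    ("bone_mineral_content", bone_mineral_content)):
        _require(v >= 0, name, "must be non-negative")
    d = constants.body_volume_densities
    fat_kg = dxa_fat_pct / 100.0 * body_mass
    return fat_kg / d.fat + lean_soft_mass / d.lean_soft + bone_mineral_content / d.bmc


def bia_total_body_water(
    stature: float,
    resistance: float,
    body_mass: float,
    sex_code_tbw: int,
    constants: EquationConstants = DEFAULT_CONSTANTS,
) -> float:
    """Total body water (kg) from BIA resistance; NOTE male = 1 here."""
    _require(stature > 0, "stature", "must be strictly positive")
    _require(resistance > 0, "resistance", "must be strictly positive")
    _require(body_mass > 0, "body_mass", "must be strictly positive")
    _require(sex_code_tbw in (0, 1), "sex_code_tbw", "must be 0 or 1")
    c = constants.tbw
    return (c.intercept + c.impedance_coef * stature ** 2 / resistance
            + c.mass_coef * body_mass + c.sex_coef * sex_code_tbw)


def four_component_inputs_from_record(
    record: ParticipantRecord,
    constants: EquationConstants = DEFAULT_CONSTANTS,
) -> FourComponentInputs:
    """Chain DXA body volume and BIA water into the 4C ingredient bundle."""
    bv = dxa_body_volume(record.dxa_fat_pct, record.body_mass,
                         record.lean_soft_mass, record.bone_mineral_content,
                         constants)
    tbw = bia_total_body_water(record.stature, record.resistance,
                               record.body_mass, record.sex_code_tbw, constants)
    return FourComponentInputs(
        body_volume=bv,
        total_body_water=tbw,
        bone_mineral_content=record.bone_mineral_content,
        body_mass=record.body_mass,
    )


def estimate_all(
    record: ParticipantRecord,
    constants: EquationConstants = DEFAULT_CONSTANTS,
) -> FatMassEstimates:
    """Compute the three FM% estimates for one participant.

    Any FM% outside [0, 100] is reported in ``flags`` (never clamped).
    Component errors are re-raised with the participant id attached.
    """
    try:
        fm_anthro = evans_fm_percent(record.skinfold_sum, record.sex_code_evans,
                                     record.race_code, constants)
        fm_us = evans_fm_percent(record.us_derived_skinfold_sum,
                                 record.sex_code_evans, record.race_code,
                                 constants)
        fm_4c = wang_4c_fm_percent(
            four_component_inputs_from_record(record, constants), constants
        )
    except InvalidInputError as exc:
        raise InvalidInputError(f"participant {record.id!r}: {exc}") from exc

    flags = tuple(
        f"{name} out of [0, 100]: {value:.2f}"
        for name, value in (("fm_pct_4c", fm_4c),
                            ("fm_pct_evans_anthro", fm_anthro),
                            ("fm_pct_evans_us", fm_us))
        if not 0.0 <= value <= 100.0
    )
    return FatMassEstimates(
        id=record.id,
        fm_pct_4c=fm_4c,
        fm_pct_evans_anthro=fm_anthro,
        fm_pct_evans_us=fm_us,
        flags=flags,
    )
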