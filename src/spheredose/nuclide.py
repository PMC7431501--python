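"""Decay kinetics, MIRD single-compartment planning and embolic-burden math.

The planning chain for glass microsphere radioembolization is arithmetic on
three constants of the nuclide and two of the device: the half-life T_half,
the mean beta energy per decay E_mean, the absorbed-dose constant Delta
(joules delivered to tissue per GBq present at implantation, assuming
permanent implantation and complete local absorption), the microsphere
diameter and the per-sphere activity at the vial calibration date.

Internally times are hours, activities GBq, doses Gy; the functions accept
days where the clinical workflow uses days (``*_days`` arguments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

MEV_TO_J = 1.602176634e-13
HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class RadionuclideSpec:
    """Physical constants of a pure beta emitter (defaults: yttrium-90).

    ``dose_constant_j_per_gbq`` and ``mean_energy_mev`` are redundant
    (Delta = E_mean * decays-to-infinity per GBq) and are required to agree
    within 1%; both are kept because the planning literature quotes Delta
    while kernel generation needs the spectrum mean.
    """

    half_life_h: float = 64.05
    mean_energy_mev: float = 0.9327
    dose_constant_j_per_gbq: float = 49.67

    def __post_init__(self):
        if self.half_life_h <= 0 or self.mean_energy_mev <= 0 or self.dose_constant_j_per_gbq <= 0:
            raise ValueError("half-life, mean energy and dose constant must all be positive")
        derived = self.derived_dose_constant_j_per_gbq
        if abs(derived - self.dose_constant_j_per_gbq) / derived > 0.01:
            raise ValueError(
                f"dose constant {self.dose_constant_j_per_gbq} J/GBq inconsistent with "
                f"mean energy {self.mean_energy_mev} MeV (implies {derived:.3f} J/GBq)"
            )

    @property
    def decay_constant_per_s(self) -> float:
        return math.log(2.0) / (self.half_life_h * 3600.0)

    @property
    def decays_per_gbq(self) -> float:
        """Total decays from 1 GBq present now, integrated to infinity."""
        return 1e9 / self.decay_constant_per_s

    @property
    def derived_dose_constant_j_per_gbq(self) -> float:
        return self.mean_energy_mev * MEV_TO_J * self.decays_per_gbq


@dataclass(frozen=True)
class DeviceSpec:
    """Glass-microsphere device constants (TheraSphere-like defaults)."""

    sphere_diameter_um: float = 27.5
    sphere_activity_bq_at_calibration: float = 2500.0
    min_unit_dosage_gbq: float = 3.0

    def __post_init__(self):
        for name in ("sphere_diameter_um", "sphere_activity_bq_at_calibration", "min_unit_dosage_gbq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def sphere_volume_ml(self) -> float:
        # (pi/6) d^3; 1 um^3 = 1e-12 mL
        return math.pi / 6.0 * self.sphere_diameter_um ** 3 * 1e-12


@dataclass(frozen=True)
class TreatmentRecord:
    """One infusion: activity at treatment time plus planning geometry."""

    infused_activity_gbq: float
    days_post_calibration: float
    target_region_volume_ml: float
    perfused_fraction: float = 1.0
    tissue_density_g_per_ml: float = 1.03
    target_dose_gy: float | None = None
    label: str = ""

    def __post_init__(self):
        if self.infused_activity_gbq < 0:
            raise ValueError("infused activity must be >= 0")
        if self.days_post_calibration < 0:
            raise ValueError("days post-calibration must be >= 0")
        if self.target_region_volume_ml <= 0:
            raise ValueError("target region volume must be positive")
        if not 0.0 < self.perfused_fraction <= 1.0:
            raise ValueError("perfused fraction must be in (0, 1]")

    @property
    def perfused_mass_kg(self) -> float:
        return (self.target_region_volume_ml * self.perfused_fraction
                * self.tissue_density_g_per_ml * 1e-3)


# -- decay kinetics ------------------------------------------------------

def decay_factor(spec: RadionuclideSpec, elapsed_h: float) -> float:
    """Fraction of activity remaining after ``elapsed_h`` hours: 2^(-t/T_half)."""
    if elapsed_h < 0:
        raise ValueError("elapsed time must be >= 0; use activity_at for back-decay")
    return 2.0 ** (-elapsed_h / spec.half_life_h)


def activity_at(spec: RadionuclideSpec, activity_gbq: float, elapsed_h: float) -> float:
    """Decay-correct an activity forward (elapsed > 0) or backward (< 0) in time."""
    if activity_gbq < 0:
        raise ValueError("activity must be >= 0")
    return activity_gbq * 2.0 ** (-elapsed_h / spec.half_life_h)


def cumulative_dose_fraction(spec: RadionuclideSpec, elapsed_h: float) -> float:
    """Fraction of the infinite-time absorbed dose delivered by ``elapsed_h``.

    With permanent implantation the dose rate tracks activity, so the
    delivered fraction is 1 - 2^(-t/T_half); ~90% of the dose is in by nine
    days for yttrium-90.
    """
    if elapsed_h < 0:
        raise ValueError("elapsed time must be >= 0")
    return 1.0 - 2.0 ** (-elapsed_h / spec.half_life_h)


# -- MIRD single-compartment planning ------------------------------------

def mird_dose(spec: RadionuclideSpec, activity_gbq: float, region_mass_kg: float) -> float:
    """Infinite-time absorbed dose (Gy) to a compartment of mass ``region_mass_kg``
    that permanently traps ``activity_gbq`` uniformly: D = Delta * A / m."""
    if region_mass_kg <= 0:
        raise ValueError("region mass must be positive")
    if activity_gbq < 0:
        raise ValueError("activity must be >= 0")
    return spec.dose_constant_j_per_gbq * activity_gbq / region_mass_kg


def activity_for_target_dose(spec: RadionuclideSpec, target_dose_gy: float,
                             region_mass_kg: float) -> float:
    """Exact inverse of :func:`mird_dose`."""
    if region_mass_kg <= 0:
        raise ValueError("region mass must be positive")
    if target_dose_gy < 0:
        raise ValueError("target dose must be >= 0")
    return target_dose_gy * region_mass_kg / spec.dose_constant_j_per_gbq


# -- microsphere-count / embolic-volume accounting -----------------------

def sphere_count_at_treatment(spec: RadionuclideSpec, device: DeviceSpec,
                              infused_activity_gbq: float,
                              days_post_calibration: float) -> float:
    """Number of microspheres implied by the treatment-day activity.

    The per-sphere activity is specified at calibration, so the infused
    activity is decay-corrected *back* to the calibration date before
    dividing. Returned as a real number; round only for display.
    """
    if infused_activity_gbq < 0 or days_post_calibration < 0:
        raise ValueError("inputs must be >= 0")
    cal_activity_bq = activity_at(
        spec, infused_activity_gbq, -days_post_calibration * HOURS_PER_DAY) * 1e9
    return cal_activity_bq / device.sphere_activity_bq_at_calibration


def embolic_volume_ml(device: DeviceSpec, sphere_count: float) -> float:
    """Total physical glass volume (mL) — the embolic burden proxy."""
    if sphere_count < 0:
        raise ValueError("sphere count must be >= 0")
    return sphere_count * device.sphere_volume_ml


@dataclass(frozen=True)
class ReductionPlan:
    """Result of planning a manual vial reduction."""

    retained_fraction: float
    activity_at_reduction_gbq: float
    activity_at_treatment_gbq: float
    max_achievable_gbq: float


def plan_unit_reduction(spec: RadionuclideSpec, device: DeviceSpec,
                        desired_treatment_activity_gbq: float,
                        treatment_days_post_calibration: float,
                        reduction_days_before_calibration: float = 0.0) -> ReductionPlan:
    """Fraction of the smallest stock vial to retain at manual reduction.

    The retained fraction is time-invariant (decay acts on retained and
    discarded spheres alike), so f = A_desired / (A_vial * 2^(-t/T_half))
    where A_vial is the unit dosage at calibration and t the treatment
    delay. The reduction date only sets the activity handled at the bench,
    reported for radiation-safety bookkeeping.
    """
    if desired_treatment_activity_gbq <= 0:
        raise ValueError("desired treatment activity must be positive")
    if treatment_days_post_calibration < 0 or reduction_days_before_calibration < 0:
        raise ValueError("times must be >= 0")
    max_achievable = activity_at(spec, device.min_unit_dosage_gbq,
                                 treatment_days_post_calibration * HOURS_PER_DAY)
    fraction = desired_treatment_activity_gbq / max_achievable
    if fraction > 1.0 + 1e-12:
        raise ValueError(
            f"requested {desired_treatment_activity_gbq} GBq exceeds the "
            f"{max_achievable:.4f} GBq a full {device.min_unit_dosage_gbq} GBq vial "
            f"decays to by treatment day"
        )
    vial_at_reduction = activity_at(spec, device.min_unit_dosage_gbq,
                                    -reduction_days_before_calibration * HOURS_PER_DAY)
    return ReductionPlan(
        retained_fraction=min(fraction, 1.0),
        activity_at_reduction_gbq=fraction * vial_at_reduction,
        activity_at_treatment_gbq=desired_treatment_activity_gbq,
        max_achievable_gbq=max_achievable,
    )


#: evaluated yttrium-90 constants used everywhere by default
Y90 = RadionuclideSpec()
THERASPHERE = DeviceSpec()
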