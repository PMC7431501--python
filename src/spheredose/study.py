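"""Published per-animal treatment parameters from the canine cerebral
radioembolization study the package models.

Three healthy research dogs (R1–R3, treated from the internal carotid,
middle and posterior cerebral arteries) and five patient dogs with
spontaneous intra-axial masses (P1–P5, all treated from the internal
carotid artery) received ⁹⁰Y glass microspheres. The infused activities and
treatment delays below are inputs to the planning math; the PET-derived
mean absorbed doses to the mass and to uninvolved cortex feed the T:N
ratio. P5 died 15 h after treatment, so its "extended" (infinite-time)
doses were never delivered; the delivered fraction at death is
``cumulative_dose_fraction(15 h)``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class StudyTreatment:
    label: str
    infused_activity_gbq: float
    days_post_calibration: float
    #: PET-based mean absorbed dose to the mass (Gy, extended); None for
    #: research dogs (no mass)
    mass_mean_dose_gy: float | None = None
    #: PET-based mean absorbed dose to uninvolved cortex (Gy, extended)
    cortex_mean_dose_gy: float | None = None
    #: pre-treatment mass volume (mL) from MR volumetry
    pre_treatment_mass_volume_ml: float | None = None
    #: MIRD single-compartment planning dose (Gy)
    single_compartment_dose_gy: float | None = None
    survival_truncation_h: float | None = None


RESEARCH_DOGS = (
    StudyTreatment("R1", 0.019, 10, single_compartment_dose_gy=27.9),
    StudyTreatment("R2", 0.025, 10, single_compartment_dose_gy=66.5),
    StudyTreatment("R3", 0.016, 10, single_compartment_dose_gy=73.0),
)

PATIENT_DOGS = (
    StudyTreatment("P1", 0.0183, 11, mass_mean_dose_gy=45.5, cortex_mean_dose_gy=15.4,
                   pre_treatment_mass_volume_ml=2.76, single_compartment_dose_gy=34.9),
    StudyTreatment("P2", 0.0478, 5, mass_mean_dose_gy=57.6, cortex_mean_dose_gy=27.6,
                   pre_treatment_mass_volume_ml=5.82, single_compartment_dose_gy=63.7),
    StudyTreatment("P3", 0.0351, 10, mass_mean_dose_gy=58.1, cortex_mean_dose_gy=19.2,
                   pre_treatment_mass_volume_ml=3.53, single_compartment_dose_gy=45.0),
    StudyTreatment("P4", 0.0414, 5, mass_mean_dose_gy=45.4, cortex_mean_dose_gy=16.7,
                   pre_treatment_mass_volume_ml=8.66, single_compartment_dose_gy=45.2),
    StudyTreatment("P5", 0.0486, 8, mass_mean_dose_gy=64.1, cortex_mean_dose_gy=33.3,
                   pre_treatment_mass_volume_ml=8.48, single_compartment_dose_gy=62.2,
                   survival_truncation_h=15.0),
)

ALL_TREATMENTS = RESEARCH_DOGS + PATIENT_DOGS
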