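"""Design summary of the multi-center OCD-DBS study setting.

The pipeline was designed around a four-cohort retrospective setting:
two training/cross-validation cohorts (ALIC and STN targets, one
stimulation setting per patient) and two test cohorts (an NAcc cohort in
which each of four contact pairs was activated for three months, giving
four outcome data points per patient, and a dual-target cohort with four
electrodes per patient). Per-patient imaging and outcomes of such studies
are not publicly distributable, so this module records only the cohort
*structure* — patient, electrode and data-point counts — which the
bookkeeping helpers re-derive from the rows rather than hard-coding
totals.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CohortDesign", "study_cohorts", "study_totals"]


@dataclass(frozen=True)
class CohortDesign:
    name: str
    target: str
    n_patients: int
    electrodes_per_patient: int
    stim_settings_per_patient: int  # outcome data points contributed per patient


def study_cohorts() -> list[CohortDesign]:
    return [
        CohortDesign("ALIC", "anterior limb of the internal capsule", 22, 2, 1),
        CohortDesign("STN", "subthalamic nucleus", 14, 2, 1),
        CohortDesign("NAcc", "nucleus accumbens", 8, 2, 4),
        CohortDesign("combined", "ALIC + STN (four electrodes)", 6, 4, 1),
    ]


def study_totals() -> dict[str, int]:
    """Patient, electrode and stimulation-data-point totals across cohorts."""
    cohorts = study_cohorts()
    return {
        "n_cohorts": len(cohorts),
        "n_patients": sum(c.n_patients for c in cohorts),
        "n_electrodes": sum(c.n_patients * c.electrodes_per_patient for c in cohorts),
        "n_stim_datapoints": sum(c.n_patients * c.stim_settings_per_patient for c in cohorts),
    }
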