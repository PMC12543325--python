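"""Shared desk-scale study conditions for the numbered analysis drivers.

Two arms (saline control vs pulsed-pressor BPV), 5 baseline + 10 treatment
days, 1-hr pulses every 3 hr with the calibrated pressor amplitudes, reflex
blunting in the treated arm, and fixed seeds throughout.
"""

from bpvkit.simulate import CircadianProfile, PressorKinetics, simulate_study_cohort

SEED = 2024
N_CONTROL = 3
N_BPV = 3
BASELINE_DAYS = 5
TREATMENT_DAYS = 10
CYCLE_HOURS = 3.0
EARLY_DAYS = (3, 5)
LATE_DAYS = (8, 10)

KINETICS = PressorKinetics(gain_decline_per_day=0.02)
CIRCADIAN = CircadianProfile()


def study_cohort():
    return simulate_study_cohort(
        n_control=N_CONTROL,
        n_bpv=N_BPV,
        baseline_days=BASELINE_DAYS,
        treatment_days=TREATMENT_DAYS,
        cycle_hours=CYCLE_HOURS,
        kinetics=KINETICS,
        circadian=CIRCADIAN,
        seed=SEED,
    )
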