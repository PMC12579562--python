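"""Published US registry reference values used as analysis inputs.

These are inputs to the counterfactual projection and calibration reference
points for the synthetic generator; real registry microdata is not
redistributable, so matched-cohort table values are carried here as plain
constants.
"""

from .counterfactual_projection import ProjectionInputs, interpolate_survival

#: 2023 US deceased-donor kidney transplant volumes
TRANSPLANT_VOLUMES_2023 = {"single": 18_873, "dual": 184}

#: matched-cohort Cox hazard ratios, dual vs single (multivariable)
DEATH_CENSORED_GRAFT_HR = 0.73
DEATH_CENSORED_GRAFT_HR_CI95 = (0.58, 0.93)
ALL_CAUSE_GRAFT_HR = 0.79
ALL_CAUSE_GRAFT_HR_CI95 = (0.68, 0.92)
PATIENT_SURVIVAL_HR = 0.85
PATIENT_SURVIVAL_HR_CI95 = (0.72, 1.01)

#: single-group death-censored graft survival at tabulated years
SINGLE_DEATH_CENSORED_SURVIVAL = {1: 0.941, 2: 0.914, 4: 0.857, 6: 0.799}

#: matched-cohort binary outcomes as (events, n) per group
MATCHED_OUTCOME_COUNTS = {
    "dgf": {"dual": (399, 1015), "single": (964, 3045)},
    "rejection_6m": {"dual": (28, 727), "single": (122, 2242)},
    "rejection_1y": {"dual": (35, 662), "single": (148, 1968)},
}

#: matched-cohort group sizes (3:1 matching)
MATCHED_N = {"dual": 1015, "single": 3045}


def reference_projection_inputs(horizon_years: float = 5.0) -> ProjectionInputs:
    """Projection inputs from the published 2023 volumes, the death-censored
    hazard ratio, and single-graft survival log-interpolated at the horizon."""
    s = interpolate_survival(SINGLE_DEATH_CENSORED_SURVIVAL, horizon_years)
    return ProjectionInputs(
        n_single=TRANSPLANT_VOLUMES_2023["single"],
        n_dual=TRANSPLANT_VOLUMES_2023["dual"],
        hr_dual_vs_single=DEATH_CENSORED_GRAFT_HR,
        hr_ci95=DEATH_CENSORED_GRAFT_HR_CI95,
        horizon_years=horizon_years,
        single_survival_at_horizon=s,
    )
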