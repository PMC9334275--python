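"""Synthetic calibration constants for the cohort simulator.

These numbers are SYNTHETIC: the mechanism parameters of the individual-based
simulation (encounter rates, hazards, size thresholds, noise) are not
measured quantities — no study reports them — but calibration choices fixed
once so that a default four-treatment, eight-week run loses roughly two
thirds of its larvae to cannibalism, the qualitative attrition shape of the
interaction experiment the generator emulates.  They are never to be read
as estimates of real damselfly biology.
"""

SYNTHETIC_COHORT_DEFAULTS = {
    # experimental design (these four ARE the study design)
    "n_per_container": 10,
    "n_containers": 10,
    "duration_days": 56,          # eight weeks, four two-week cycles
    # synthetic biology (calibration constants)
    "init_hw_mean": 1.2,          # mm, plausible mid-instar head width
    "init_hw_cv": 0.10,           # lognormal CV of initial head width
    "growth_noise_sd": 0.01,      # day⁻¹ sd on the daily log-growth increment
    "intrinsic_hazard": 0.0005,   # per-day non-cannibalism death probability
    "encounter_rate_ref": 2.5,    # expected pairwise encounters/container/day at 23 °C
    "activity_q10": 2.0,          # fold change of encounter rate per 10 °C
    "size_ratio_threshold": 1.15, # minimum cannibal/victim head-width ratio for a kill
}
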