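"""Canonical feature-name catalogue for lumbar-gait / wrist-activity panels.

Eleven daily gait summaries from a lumbar accelerometer and thirteen daily
physical-activity (PA) summaries from a wrist accelerometer.  These names are
used by the synthetic generator so that reports produced from simulated data
look like reports produced from a real deployment.
"""

GAIT_FEATURES: tuple[str, ...] = (
    "total_step_per_day",
    "total_bout_length",
    "gait_speed",
    "cadence",
    "stance",
    "swing",
    "stride_duration",
    "double_support",
    "single_limb_support",
    "stride_length",
    "gait_speed_95perc",
)

PA_FEATURES: tuple[str, ...] = (
    "sedentary",
    "light",
    "moderate",
    "vigorous",
    "sleep_time",
    "sed_period",
    "light_period",
    "mod_period",
    "mean_SVMg",
    "perc95_SVMg",
    "max_6min",
    "max_15min",
    "max_60min",
)

#: feature -> domain label, for building domain maps
DEFAULT_DOMAIN_MAP: dict[str, str] = {
    **{f: "gait" for f in GAIT_FEATURES},
    **{f: "PA" for f in PA_FEATURES},
}
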