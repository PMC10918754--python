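"""Shared label sets: intrinsic networks, executive-function tasks, factors.

The five intrinsic networks follow the Brainnetome-style organization of 246
regions (central executive, default mode, salience, limbic, dorsal
attention); regions outside the five named networks are carried under
``unassigned`` and count toward whole-brain summaries only.
"""

from __future__ import annotations

NETWORKS: tuple[str, ...] = ("CEN", "DMN", "SN", "LN", "DA")
UNASSIGNED = "unassigned"
ALL_NETWORK_GROUPS: tuple[str, ...] = NETWORKS + (UNASSIGNED,)
WHOLE_BRAIN = "whole_brain"

FACTORS: tuple[str, ...] = (
    "cognitive_flexibility",
    "inhibitory_control",
    "processing_speed",
    "working_memory",
)

#: The 14 executive-function task scores, in canonical column order.
INDICATORS: tuple[str, ...] = (
    "CST", "LF", "CF", "TMT-B", "CS",
    "CWI-I", "CWI-S",
    "TMT-A", "TMT-MS", "RT",
    "0-back", "1-back", "2-back", "CPT",
)

#: Indicator -> latent factor (correlated four-factor structure).
FACTOR_PATTERN: dict[str, str] = {
    "CST": "cognitive_flexibility",
    "LF": "cognitive_flexibility",
    "CF": "cognitive_flexibility",
    "TMT-B": "cognitive_flexibility",
    "CS": "cognitive_flexibility",
    "CWI-I": "inhibitory_control",
    "CWI-S": "inhibitory_control",
    "TMT-A": "processing_speed",
    "TMT-MS": "processing_speed",
    "RT": "processing_speed",
    "0-back": "working_memory",
    "1-back": "working_memory",
    "2-back": "working_memory",
    "CPT": "working_memory",
}

#: Indicator -> administered task battery/subtest family.  Residual
#: covariances may only be freed between indicators sharing both the task
#: and the factor.
TASK_OF: dict[str, str] = {
    "CST": "card_sorting",
    "LF": "verbal_fluency",
    "CF": "verbal_fluency",
    "CS": "verbal_fluency",
    "TMT-A": "trail_making",
    "TMT-B": "trail_making",
    "TMT-MS": "trail_making",
    "CWI-I": "color_word_interference",
    "CWI-S": "color_word_interference",
    "RT": "conditional_exclusion",
    "0-back": "n_back",
    "1-back": "n_back",
    "2-back": "n_back",
    "CPT": "continuous_performance",
}

#: Time-based scores (seconds / milliseconds): lower raw values mean better
#: performance, so they are sign-flipped before entering the factor model.
TIMED_INDICATORS: frozenset[str] = frozenset({
    "TMT-A", "TMT-B", "TMT-MS", "CWI-I", "CWI-S",
    "RT", "0-back", "1-back", "2-back", "CPT",
})

#: Mean ages of the four age cohorts used to probe simple slopes.
COHORT_MEAN_AGES: tuple[float, ...] = (13.17, 27.01, 50.09, 69.42)
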