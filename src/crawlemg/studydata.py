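"""Tabulated bookkeeping of the 10-participant crawling study being emulated.

These small count tables are inputs to the analysis, not outputs of it: the
per-participant numbers of segmented crawling cycles for the eight predefined
coordination modes and for the self-selected mode at each speed, and the
per-speed classification counts of the self-selected cycles.  They anchor the
pipeline's bookkeeping arithmetic (total sample counts, held-out test-set
sizes, per-speed mode proportions) and the scale parameters of the synthetic
cohort generator.
"""

from __future__ import annotations

PARTICIPANTS = tuple(f"P{i}" for i in range(1, 11))

#: segmented crawling cycles per participant over all eight predefined modes
PREDEFINED_CYCLE_COUNTS: dict[str, dict[str, int]] = {
    "low":    dict(zip(PARTICIPANTS, (95, 66, 85, 93, 81, 92, 86, 88, 104, 109))),
    "medium": dict(zip(PARTICIPANTS, (105, 77, 90, 96, 85, 95, 98, 90, 91, 109))),
    "fast":   dict(zip(PARTICIPANTS, (102, 63, 96, 97, 85, 86, 91, 82, 87, 112))),
}

#: segmented crawling cycles per participant in the self-selected mode
SELF_SELECTED_CYCLE_COUNTS: dict[str, dict[str, int]] = {
    "low":    dict(zip(PARTICIPANTS, (10, 9, 8, 9, 8, 10, 9, 10, 10, 11))),
    "medium": dict(zip(PARTICIPANTS, (11, 11, 10, 10, 8, 9, 9, 10, 11, 10))),
    "fast":   dict(zip(PARTICIPANTS, (10, 8, 10, 9, 10, 9, 9, 10, 10, 10))),
}

#: self-selected cycles assigned to each mode per speed by the study's
#: mixed-speed multi-participant KNN model (modes absent from a speed omitted)
SELF_SELECTED_CLASSIFIED: dict[str, dict[str, int]] = {
    "low":    {"M2": 87, "M3": 9},
    "medium": {"M2": 92},
    "fast":   {"M2": 68, "M3": 23},
}

#: left-palm phase statistics of self-selected crawling, mean ± sd
STANCE_DURATION_S = {"low": (1.437, 0.255), "medium": (1.009, 0.220),
                     "fast": (0.717, 0.135)}
SWING_DURATION_S = {"low": (0.601, 0.149), "medium": (0.531, 0.078),
                    "fast": (0.496, 0.089)}
DUTY_FACTOR_PCT = {"low": (70.40, 6.54), "medium": (64.97, 5.32),
                   "fast": (58.98, 4.81)}


def total_predefined_cycles() -> int:
    """Total predefined-mode cycles across all participants and speeds."""
    return sum(sum(v.values()) for v in PREDEFINED_CYCLE_COUNTS.values())


def participant_predefined_cycles(participant: str) -> int:
    """Predefined-mode cycles of one participant across the three speeds
    (the test-set size when that participant is held out at mixed speed)."""
    return sum(v[participant] for v in PREDEFINED_CYCLE_COUNTS.values())


def self_selected_total(speed: str) -> int:
    return sum(SELF_SELECTED_CYCLE_COUNTS[speed].values())
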