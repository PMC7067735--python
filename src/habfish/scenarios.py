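"""Water-clarity scenario levels.

Scenarios are expressed as percent relative change in summer Secchi
depth against the initial (0%) condition: one deterioration level, the
baseline, and five improvement levels. +11% is the policy target and
+48% the reference (pre-eutrophication) level for the study basin.
"""

from __future__ import annotations

SCENARIO_LEVELS: tuple = (-10, 0, 11, 20, 30, 40, 48)
BASELINE_LEVEL: int = 0
TARGET_LEVEL: int = 11
REFERENCE_LEVEL: int = 48


def validate_levels(levels) -> tuple:
    """Check a scenario list: numeric, unique, containing the 0% baseline."""
    lv = tuple(float(x) if x % 1 else int(x) for x in levels)
    if len(set(lv)) != len(lv):
        raise ValueError(f"duplicate scenario levels in {levels}")
    if BASELINE_LEVEL not in lv:
        raise ValueError("scenario levels must include the 0% baseline")
    return lv
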