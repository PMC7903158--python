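"""Constants of the dichotic-listening trial design.

A trial presents a visual temporal cue, then an auditory spatial cue (left or
right ear) at t = 0, then five pairs of competing spoken numbers. Number
onsets are spaced 1.25 s apart starting 1.5 s after spatial-cue onset, giving
a stimulus presentation rate of 0.8 Hz. At the end of the trial one number
position is probed; on instructive-cue trials the cued position is probed
with 70% probability ("valid"), otherwise another position is probed
("invalid").
"""

from __future__ import annotations

N_TRIALS_DEFAULT = 160
N_POSITIONS = 5

#: onset of the first number relative to spatial-cue onset (s)
FIRST_ONSET_S = 1.5
#: onset-to-onset interval of successive numbers (s)
ONSET_INTERVAL_S = 1.25
#: number presentation rate (Hz) = 1 / ONSET_INTERVAL_S
STIM_RATE_HZ = 0.8

#: how often each position is cued among the 80 instructive trials
POSITION_CUE_COUNTS = {1: 8, 2: 18, 3: 28, 4: 18, 5: 8}

#: probability that the cued position is the probed one
CUE_VALIDITY = 0.7

#: epoch support relative to spatial-cue onset (s)
EPOCH_WINDOW_S = (-2.0, 10.0)

CUE_TYPES = ("instructive", "neutral")
SIDES = ("left", "right")


def number_onset(position: int) -> float:
    """Onset time (s, relative to spatial-cue onset) of a number position 1-5."""
    if not 1 <= position <= N_POSITIONS:
        raise ValueError(f"position must be 1..{N_POSITIONS}, got {position}")
    return FIRST_ONSET_S + ONSET_INTERVAL_S * (position - 1)
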