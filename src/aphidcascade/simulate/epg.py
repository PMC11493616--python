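"""Semi-Markov surrogate for annotated EPG recordings.

A continuous-time semi-Markov chain over the six waveform states stands
in for a real recording: sojourn times are exponential at the profile's
per-state means (floored at ``min_sojourn`` so bouts stay resolvable on
a 1-s grid), the next state is drawn from the profile's transition
weights, the chain starts in Np (the aphid begins off the plant), and
the final bout is truncated at the recording duration.  Only the event-
log format and the downstream parameter arithmetic mirror real EPG data;
no waveform biophysics is modelled.
"""

from __future__ import annotations

import numpy as np

from aphidcascade.epg import EpgRecording, Segment
from aphidcascade.profiles import ProfileError, TreatmentProfile

__all__ = ["gen_epg_recording"]


def gen_epg_recording(
    profile: TreatmentProfile,
    duration: float = 28800.0,
    seed: int | None = None,
    recording_id: str | None = None,
) -> EpgRecording:
    """Simulate one annotated recording of ``duration`` seconds."""
    if duration <= 0:
        raise ProfileError("duration must be > 0")
    profile.validate()
    rng = np.random.default_rng(seed)
    rates = profile.epg

    # Precompute normalised transition tables for the reachable states.
    table = {
        state: (list(weights.keys()), np.array(list(weights.values()), dtype=float))
        for state, weights in rates.transitions.items()
    }
    for state, (targets, w) in table.items():
        table[state] = (targets, w / w.sum())

    segments = []
    t = 0.0
    state = "Np"
    while t < duration:
        sojourn = max(rng.exponential(rates.sojourn_means[state]), rates.min_sojourn)
        end = min(t + sojourn, duration)
        if duration - end < rates.min_sojourn:
            # absorb a trailing remainder shorter than min_sojourn into the
            # final (truncated) bout so every bout stays grid-resolvable
            end = duration
        segments.append(Segment(t, end, state))
        t = end
        if t >= duration:
            break
        if state not in table:
            raise ProfileError(f"state {state!r} has no outgoing transitions but time remains")
        targets, w = table[state]
        state = targets[int(rng.choice(len(targets), p=w))]
    rec_id = recording_id if recording_id is not None else f"{profile.name}-epg"
    return EpgRecording(recording_id=rec_id, duration=float(duration), segments=tuple(segments))
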