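"""EPG event-log parsing and feeding-behaviour parameter extraction.

Electrical penetration graph (EPG) recordings wire an aphid into a
circuit with its host plant; the voltage trace is scored into waveform
bouts from the closed set {Np, C, Pd, E1, E2, G} (non-probing, pathway,
intracellular puncture, phloem salivation, phloem ingestion, xylem
ingestion).  This module consumes annotated event logs — a plain-text
stand-in for the proprietary ANA export, one row per bout onset — and
computes the standard per-insect parameters: waveform event counts, total
durations, and times to first E1/E2.

Latencies are measured from the recording start (t = 0) by default;
pass ``latency_from="first-probe"`` to measure from the first stylet
contact (first non-Np segment) instead.  Recordings without any E1 (or
E2) have undefined latency and are excluded from latency group means
rather than imputed at the recording length; group SEs use the n-1
denominator, so a single-recording group reports SE = NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from aphidcascade.profiles import WAVEFORMS

__all__ = [
    "Segment",
    "EpgRecording",
    "EpgParameterSet",
    "EpgParseError",
    "parse_event_log",
    "compute_parameters",
    "parameters_table",
    "group_summary",
    "write_event_log",
]


class EpgParseError(ValueError):
    """Raised when an event log violates the dialect contract."""


class Segment(NamedTuple):
    start: float
    end: float
    waveform: str


@dataclass(frozen=True)
class EpgRecording:
    """One annotated recording: contiguous labelled segments over [0, duration]."""

    recording_id: str
    duration: float
    segments: tuple[Segment, ...]

    def __post_init__(self):
        if self.duration <= 0:
            raise EpgParseError(f"recording {self.recording_id!r}: duration must be > 0")
        if not self.segments:
            raise EpgParseError(f"recording {self.recording_id!r}: no segments")
        if self.segments[0].start != 0:
            raise EpgParseError(f"recording {self.recording_id!r}: first segment must start at 0")
        prev_end = 0.0
        for seg in self.segments:
            if seg.waveform not in WAVEFORMS:
                raise EpgParseError(
                    f"recording {self.recording_id!r}: unknown waveform {seg.waveform!r}"
                )
            if seg.start != prev_end:
                raise EpgParseError(
                    f"recording {self.recording_id!r}: gap/overlap at t={seg.start}"
                )
            if seg.end <= seg.start:
                raise EpgParseError(
                    f"recording {self.recording_id!r}: non-positive segment at t={seg.start}"
                )
            prev_end = seg.end
        if prev_end != self.duration:
            raise EpgParseError(
                f"recording {self.recording_id!r}: segments end at {prev_end}, not duration {self.duration}"
            )


@dataclass(frozen=True)
class EpgParameterSet:
    """Per-recording feeding parameters.

    ``counts[w]`` is the number of maximal bouts of waveform ``w``;
    ``durations[w]`` their summed length in seconds (they conserve the
    recording duration); latencies are None when the waveform is absent.
    """

    recording_id: str
    counts: dict[str, int]
    durations: dict[str, float]
    time_to_first_E1: float | None
    time_to_first_E2: float | None


def parse_event_log(src, duration: float = 28800.0) -> list[EpgRecording]:
    """Parse an event-log CSV into recordings.

    Expects columns ``recording_id, onset_s, waveform``; onsets strictly
    increasing within a recording, starting at 0; each segment ends at
    the next onset (or ``duration`` for the last).  Errors name the
    offending CSV row (1-based, excluding the header).
    """
    if duration <= 0:
        raise EpgParseError("duration must be > 0")
    df = pd.read_csv(src, float_precision="round_trip")
    required = {"recording_id", "onset_s", "waveform"}
    missing = required - set(df.columns)
    if missing:
        raise EpgParseError(f"event log missing columns: {sorted(missing)}")
    df = df.reset_index(drop=True)
    df["_row"] = df.index + 1
    recordings = []
    for rec_id, grp in df.groupby("recording_id", sort=False):
        onsets = grp["onset_s"].to_numpy(dtype=float)
        labels = list(grp["waveform"])
        rows = grp["_row"].to_numpy()
        if onsets[0] != 0:
            raise EpgParseError(f"row {rows[0]}: first onset of {rec_id!r} must be 0")
        for i, (t, lab) in enumerate(zip(onsets, labels)):
            if lab not in WAVEFORMS:
                raise EpgParseError(f"row {rows[i]}: unknown waveform {lab!r}")
            if t >= duration:
                raise EpgParseError(f"row {rows[i]}: onset {t} >= duration {duration}")
            if i > 0 and t <= onsets[i - 1]:
                raise EpgParseError(f"row {rows[i]}: non-monotone onset {t}")
        ends = np.concatenate([onsets[1:], [duration]])
        segments = tuple(Segment(float(s), float(e), lab) for s, e, lab in zip(onsets, ends, labels))
        recordings.append(EpgRecording(recording_id=str(rec_id), duration=duration, segments=segments))
    if not recordings:
        raise EpgParseError("event log contains no recordings")
    return recordings


def compute_parameters(recording: EpgRecording, latency_from: str = "start") -> EpgParameterSet:
    """Counts, total durations and first-E1/E2 latencies of one recording."""
    if latency_from not in ("start", "first-probe"):
        raise ValueError("latency_from must be 'start' or 'first-probe'")
    counts = {w: 0 for w in WAVEFORMS}
    durations = {w: 0.0 for w in WAVEFORMS}
    first = {}
    for seg in recording.segments:
        counts[seg.waveform] += 1
        durations[seg.waveform] += seg.end - seg.start
        first.setdefault(seg.waveform, seg.start)
    origin = 0.0
    if latency_from == "first-probe":
        probes = [s.start for s in recording.segments if s.waveform != "Np"]
        origin = min(probes) if probes else 0.0
    t_e1 = first.get("E1")
    t_e2 = first.get("E2")
    return EpgParameterSet(
        recording_id=recording.recording_id,
        counts=counts,
        durations=durations,
        time_to_first_E1=(t_e1 - origin) if t_e1 is not None else None,
        time_to_first_E2=(t_e2 - origin) if t_e2 is not None else None,
    )


def parameters_table(
    recordings: Iterable[EpgRecording], latency_from: str = "start"
) -> pd.DataFrame:
    """One row of feeding parameters per recording."""
    rows = []
    for rec in recordings:
        ps = compute_parameters(rec, latency_from=latency_from)
        row: dict = {"recording_id": ps.recording_id}
        for w in WAVEFORMS:
            row[f"n_{w}"] = ps.counts[w]
            row[f"dur_{w}"] = ps.durations[w]
        row["time_to_first_E1"] = np.nan if ps.time_to_first_E1 is None else ps.time_to_first_E1
        row["time_to_first_E2"] = np.nan if ps.time_to_first_E2 is None else ps.time_to_first_E2
        rows.append(row)
    return pd.DataFrame(rows)


def group_summary(table: pd.DataFrame, treatments: pd.Series | list[str]) -> pd.DataFrame:
    """Per-treatment mean +/- SE of every parameter.

    Latencies are averaged over recordings where they are defined, with
    the defined count reported as ``n_time_to_first_*``.
    """
    table = table.copy()
    table["treatment"] = list(treatments)
    grouped = table.groupby("treatment", sort=False)
    if (grouped.size() < 1).any() or len(table) == 0:
        raise ValueError("every treatment group needs at least one recording")
    out = {}
    params = [c for c in table.columns if c not in ("recording_id", "treatment")]
    for col in params:
        out[f"{col}_mean"] = grouped[col].mean()
        out[f"{col}_se"] = grouped[col].sem()
    summary = pd.DataFrame(out)
    summary["n"] = grouped.size()
    for col in ("time_to_first_E1", "time_to_first_E2"):
        summary[f"n_{col}"] = grouped[col].count()
    return summary


def write_event_log(recordings: Iterable[EpgRecording], path) -> None:
    """Write recordings in the event-log CSV dialect (onset rows only)."""
    rows = [
        (rec.recording_id, seg.start, seg.waveform)
        for rec in recordings
        for seg in rec.segments
    ]
    pd.DataFrame(rows, columns=["recording_id", "onset_s", "waveform"]).to_csv(
        path, index=False, float_format="%.17g"
    )
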