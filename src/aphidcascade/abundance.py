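"""Population-abundance summaries for whole-plant aphid count series.

A survey series holds counts from ``n_reps`` caged plants recorded every
5 days from day 5 to day 55 after infestation.  The module computes the
whole-period mean abundance (the grand mean over all replicate x day
cells), percent-of-control relative abundance, and the survey day of
peak mean abundance.  Missing cells (e.g. a dead plant) are stored as
NaN and excluded from means rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SurveySeries",
    "SurveyError",
    "mean_abundance",
    "relative_abundance",
    "peak_day",
    "read_counts_csv",
    "write_counts_csv",
    "abundance_summary",
]

DEFAULT_SURVEY_DAYS = tuple(range(5, 56, 5))


class SurveyError(ValueError):
    """Raised for malformed or degenerate survey series."""


@dataclass(frozen=True)
class SurveySeries:
    """Replicate x survey-day count grid for one treatment."""

    treatment: str
    days: tuple[int, ...]
    counts: np.ndarray  # (n_reps, n_days), float with NaN for missing cells

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != len(self.days):
            raise SurveyError("counts must be a (replicates x days) grid")
        if counts.shape[0] < 1 or counts.shape[1] < 1:
            raise SurveyError("empty survey grid")
        if np.any(np.diff(self.days) <= 0):
            raise SurveyError("survey days must be strictly increasing")
        observed = counts[~np.isnan(counts)]
        if np.any(observed < 0):
            raise SurveyError("counts must be >= 0")
        object.__setattr__(self, "counts", counts)

    @property
    def n_reps(self) -> int:
        return self.counts.shape[0]


def mean_abundance(series: SurveySeries) -> float:
    """Grand mean over all observed replicate x day cells (aphids/plant)."""
    observed = series.counts[~np.isnan(series.counts)]
    if observed.size == 0:
        raise SurveyError("no observed cells")
    return float(observed.mean())


def relative_abundance(series: SurveySeries, control: SurveySeries) -> float:
    """Whole-period mean abundance as a percentage of the control's."""
    control_mean = mean_abundance(control)
    if control_mean == 0:
        raise SurveyError("control mean abundance is zero")
    return 100.0 * mean_abundance(series) / control_mean


def peak_day(series: SurveySeries) -> int:
    """Survey day with the largest replicate-mean count (earliest wins ties)."""
    with np.errstate(invalid="ignore"):
        day_means = np.nanmean(series.counts, axis=0)
    if np.all(np.isnan(day_means)):
        raise SurveyError("no observed cells")
    return int(series.days[int(np.nanargmax(day_means))])


def abundance_summary(series_by_treatment: dict[str, SurveySeries], control: str = "Control") -> pd.DataFrame:
    """Mean abundance, percent of control and peak day per treatment."""
    if control not in series_by_treatment:
        raise SurveyError(f"control treatment {control!r} not present")
    ctrl = series_by_treatment[control]
    rows = []
    for name, series in series_by_treatment.items():
        rows.append({
            "treatment": name,
            "mean_abundance": mean_abundance(series),
            "relative_abundance_pct": relative_abundance(series, ctrl),
            "peak_day": peak_day(series),
            "n_reps": series.n_reps,
        })
    return pd.DataFrame(rows)


def write_counts_csv(series_list: list[SurveySeries], path) -> None:
    """Long-format counts CSV: treatment, replicate, day, count."""
    rows = []
    for series in series_list:
        for rep in range(series.n_reps):
            for j, day in enumerate(series.days):
                value = series.counts[rep, j]
                if not np.isnan(value):
                    rows.append((series.treatment, rep + 1, day, int(value)))
    pd.DataFrame(rows, columns=["treatment", "replicate", "day", "count"]).to_csv(path, index=False)


def read_counts_csv(path) -> dict[str, SurveySeries]:
    """Read the long-format counts CSV; absent cells become NaN."""
    df = pd.read_csv(path)
    required = {"treatment", "replicate", "day", "count"}
    missing = required - set(df.columns)
    if missing:
        raise SurveyError(f"counts CSV missing columns: {sorted(missing)}")
    out = {}
    for treatment, grp in df.groupby("treatment", sort=False):
        days = tuple(sorted(grp["day"].unique()))
        reps = sorted(grp["replicate"].unique())
        grid = np.full((len(reps), len(days)), np.nan)
        day_idx = {d: j for j, d in enumerate(days)}
        rep_idx = {r: i for i, r in enumerate(reps)}
        for _, row in grp.iterrows():
            grid[rep_idx[row["replicate"]], day_idx[row["day"]]] = row["count"]
        out[str(treatment)] = SurveySeries(treatment=str(treatment), days=days, counts=grid)
    return out
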