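"""Treatment profiles for the saline-alkali stress design.

The experimental design crosses chloride salinity (NaCl at 75 and 150 mM)
with carbonate alkalinity (Na2CO3 at 5 and 12 mM, pH 8.7 and 9.5): two
single-salt levels each plus three mixed treatments and an unstressed
control, eight treatments in all.  Each :class:`TreatmentProfile` carries
everything the synthetic generators need to emulate one treatment:

* aphid life-history moments (nymph duration, adult longevity, reproductive
  days, lifetime fecundity, pre-adult survival) calibrated to the reported
  cohort summaries (n = 30 per treatment; reported SEs are converted to
  per-individual SDs via sd = se * sqrt(30));
* a semi-Markov parameterisation of an 8-h EPG recording (per-state mean
  sojourns in seconds plus transition weights over the closed waveform set
  {Np, C, Pd, E1, E2, G});
* a latent rise-then-decline curve for whole-plant aphid counts surveyed
  every 5 days to day 55, with a negative-binomial dispersion.

Pre-adult survival is not reported directly; it is derived as
R0 / fecundity, which is ~0.857 for every treatment (the two reported
summary tables are mutually consistent under that identity).

Per-state EPG rates and the latent count curves are not published as
numbers; the defaults here are documented placeholders with the reported
percent-of-control mean abundances wired in as exact amplitude ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

__all__ = [
    "WAVEFORMS",
    "TREATMENTS",
    "EpgRates",
    "TreatmentProfile",
    "ProfileError",
    "default_profiles",
    "load_profiles",
    "dump_profiles",
    "REPORTED_LIFE_HISTORY",
    "REPORTED_GROWTH_PARAMETERS",
    "REPORTED_RELATIVE_ABUNDANCE",
]

#: Closed EPG waveform label set: non-probing, pathway, intracellular
#: puncture, phloem salivation, phloem ingestion, xylem ingestion.
WAVEFORMS = ("Np", "C", "Pd", "E1", "E2", "G")

TREATMENTS = (
    "Control",
    "Salinity_middle",
    "Salinity_high",
    "Alkalinity_middle",
    "Alkalinity_high",
    "Sm_Am",
    "Sm_Ah",
    "Sh_Am",
)


class ProfileError(ValueError):
    """Raised when a treatment profile fails validation."""


# Reported life-history summaries (mean, SE; n = 30) used to calibrate the
# default profiles: nymph period (d), adult longevity (d), reproductive
# days (d), lifetime fecundity (offspring per female).
REPORTED_LIFE_HISTORY: dict[str, dict[str, tuple[float, float]]] = {
    "Control": {"nymph": (4.93, 0.16), "longevity": (25.73, 1.77), "repro_days": (15.47, 1.13), "fecundity": (34.03, 2.91)},
    "Salinity_middle": {"nymph": (5.20, 0.23), "longevity": (23.57, 1.24), "repro_days": (10.37, 0.54), "fecundity": (17.87, 1.22)},
    "Salinity_high": {"nymph": (5.30, 0.24), "longevity": (22.53, 0.98), "repro_days": (12.20, 0.78), "fecundity": (22.67, 1.86)},
    "Alkalinity_middle": {"nymph": (6.47, 0.21), "longevity": (25.87, 0.94), "repro_days": (11.30, 0.63), "fecundity": (16.90, 1.33)},
    "Alkalinity_high": {"nymph": (5.97, 0.17), "longevity": (21.53, 1.16), "repro_days": (8.90, 0.63), "fecundity": (13.97, 1.11)},
    "Sm_Am": {"nymph": (7.43, 0.45), "longevity": (25.30, 1.15), "repro_days": (9.20, 0.35), "fecundity": (15.27, 0.74)},
    "Sm_Ah": {"nymph": (6.97, 0.35), "longevity": (21.67, 1.15), "repro_days": (9.80, 0.56), "fecundity": (16.53, 0.80)},
    "Sh_Am": {"nymph": (6.57, 0.25), "longevity": (23.80, 1.01), "repro_days": (9.13, 0.82), "fecundity": (13.93, 1.70)},
}

# Reported population growth parameters (mean, SE): intrinsic rate of
# increase r (1/d), finite rate lambda (1/d), net reproductive rate R0
# (offspring/individual), mean generation time T (d).
REPORTED_GROWTH_PARAMETERS: dict[str, dict[str, tuple[float, float]]] = {
    "Control": {"r": (0.32, 0.01), "lambda": (1.38, 0.02), "R0": (29.17, 3.18), "T": (10.59, 0.48)},
    "Salinity_middle": {"r": (0.29, 0.02), "lambda": (1.34, 0.02), "R0": (15.31, 1.47), "T": (9.37, 0.30)},
    "Salinity_high": {"r": (0.30, 0.01), "lambda": (1.35, 0.02), "R0": (19.43, 2.06), "T": (9.96, 0.27)},
    "Alkalinity_middle": {"r": (0.22, 0.01), "lambda": (1.24, 0.01), "R0": (14.49, 1.50), "T": (12.34, 0.43)},
    "Alkalinity_high": {"r": (0.23, 0.01), "lambda": (1.26, 0.01), "R0": (11.97, 1.25), "T": (10.57, 0.30)},
    "Sm_Am": {"r": (0.21, 0.01), "lambda": (1.23, 0.01), "R0": (13.09, 1.09), "T": (12.37, 0.52)},
    "Sm_Ah": {"r": (0.23, 0.01), "lambda": (1.26, 0.02), "R0": (14.17, 1.19), "T": (11.64, 0.61)},
    "Sh_Am": {"r": (0.20, 0.01), "lambda": (1.22, 0.01), "R0": (11.94, 1.65), "T": (12.65, 0.46)},
}

# Reported whole-period mean abundance as percent of control.  Only the
# range 20.3-32.7% is reported for the three mixed treatments; endpoints
# are assigned by r_m ordering and Sm_Am takes the midpoint (placeholder).
REPORTED_RELATIVE_ABUNDANCE: dict[str, float] = {
    "Control": 100.0,
    "Salinity_high": 86.0,
    "Salinity_middle": 59.6,
    "Alkalinity_middle": 45.4,
    "Alkalinity_high": 19.1,
    "Sm_Ah": 32.7,
    "Sm_Am": 26.5,
    "Sh_Am": 20.3,
}

_N_REPORTED = 30  # cohort size behind the reported SEs

# NaCl / Na2CO3 concentrations (mM) per treatment.
_CONCENTRATIONS: dict[str, tuple[float, float]] = {
    "Control": (0.0, 0.0),
    "Salinity_middle": (75.0, 0.0),
    "Salinity_high": (150.0, 0.0),
    "Alkalinity_middle": (0.0, 5.0),
    "Alkalinity_high": (0.0, 12.0),
    "Sm_Am": (75.0, 5.0),
    "Sm_Ah": (75.0, 12.0),
    "Sh_Am": (150.0, 5.0),
}


@dataclass(frozen=True)
class EpgRates:
    """Semi-Markov parameterisation of an EPG recording.

    ``sojourn_means`` are per-state mean sojourn times in seconds
    (exponential draws, floored at ``min_sojourn``); ``transitions`` maps
    each state to next-state weights (self-transitions are forbidden so
    that consecutive segments always differ in label).
    """

    sojourn_means: Mapping[str, float]
    transitions: Mapping[str, Mapping[str, float]]
    min_sojourn: float = 2.0

    def validate(self) -> None:
        for state in WAVEFORMS:
            mean = self.sojourn_means.get(state)
            if mean is None or mean <= 0:
                raise ProfileError(f"sojourn mean for state {state!r} must be > 0")
        if self.min_sojourn < 0:
            raise ProfileError("min_sojourn must be >= 0")
        for state, weights in self.transitions.items():
            if state not in WAVEFORMS:
                raise ProfileError(f"unknown EPG state {state!r}")
            total = 0.0
            for target, w in weights.items():
                if target not in WAVEFORMS:
                    raise ProfileError(f"unknown EPG state {target!r}")
                if target == state and w > 0:
                    raise ProfileError(f"self-transition forbidden for state {state!r}")
                if w < 0:
                    raise ProfileError("transition weights must be >= 0")
                total += w
            if total <= 0:
                raise ProfileError(f"state {state!r} has no outgoing transition weight")


@dataclass(frozen=True)
class TreatmentProfile:
    """All generator inputs for one stress treatment.

    Duration moments are in days, fecundity in offspring per female,
    concentrations in mM, count-series parameters in aphids per plant.
    """

    name: str
    nacl: float
    na2co3: float
    nymph_mean: float
    nymph_sd: float
    adult_longevity_mean: float
    adult_longevity_sd: float
    repro_days_mean: float
    repro_days_sd: float
    fecundity_mean: float
    fecundity_sd: float
    preadult_survival: float
    epg: EpgRates
    growth_rate: float = 0.25
    carrying_capacity: float = 400.0
    decline_day: float = 35.0
    decline_rate: float = 0.08
    initial_density: float = 5.0
    nb_dispersion: float = 5.0

    def validate(self) -> None:
        if self.nacl < 0 or self.na2co3 < 0:
            raise ProfileError("concentrations must be >= 0")
        if not 0.0 <= self.preadult_survival <= 1.0:
            raise ProfileError("preadult_survival must be in [0, 1]")
        for attr in ("nymph_mean", "adult_longevity_mean", "repro_days_mean"):
            if getattr(self, attr) <= 0:
                raise ProfileError(f"{attr} must be > 0")
        if self.fecundity_mean < 0:
            raise ProfileError("fecundity_mean must be >= 0")
        for attr in ("nymph_sd", "adult_longevity_sd", "repro_days_sd", "fecundity_sd"):
            if getattr(self, attr) < 0:
                raise ProfileError(f"{attr} must be >= 0")
        if self.nb_dispersion <= 0:
            raise ProfileError("nb_dispersion must be > 0")
        for attr in ("growth_rate", "carrying_capacity", "decline_rate", "initial_density"):
            if getattr(self, attr) <= 0:
                raise ProfileError(f"{attr} must be > 0")
        self.epg.validate()


def _default_epg(relative: float) -> EpgRates:
    """Placeholder EPG rates, modulated by stress severity.

    ``relative`` is the treatment's mean abundance relative to control in
    [0, 1]; heavier stress (smaller ``relative``) lengthens non-probing
    and shortens phloem ingestion, matching the qualitative direction of
    the reported waveform contrasts.
    """
    stress = 1.0 - relative
    return EpgRates(
        sojourn_means={
            "Np": 600.0 * (1.0 + stress),
            "C": 240.0 * (1.0 + 0.4 * stress),
            "Pd": 6.0 * (1.0 + 0.5 * stress),
            "E1": 180.0,
            "E2": 1500.0 * (1.0 - 0.6 * stress),
            "G": 500.0 * (1.0 + 0.4 * stress),
        },
        transitions={
            "Np": {"C": 1.0},
            "C": {"Pd": 0.45, "E1": 0.2, "Np": 0.2, "G": 0.15},
            "Pd": {"C": 1.0},
            "E1": {"E2": 0.7, "C": 0.3},
            "E2": {"C": 0.6, "Np": 0.4},
            "G": {"C": 0.7, "Np": 0.3},
        },
    )


def default_profiles() -> dict[str, TreatmentProfile]:
    """Build the eight default treatment profiles from the reported means."""
    sqrt_n = math.sqrt(_N_REPORTED)
    profiles: dict[str, TreatmentProfile] = {}
    for name in TREATMENTS:
        hist = REPORTED_LIFE_HISTORY[name]
        growth = REPORTED_GROWTH_PARAMETERS[name]
        relative = REPORTED_RELATIVE_ABUNDANCE[name] / 100.0
        survival = growth["R0"][0] / hist["fecundity"][0]
        profiles[name] = TreatmentProfile(
            name=name,
            nacl=_CONCENTRATIONS[name][0],
            na2co3=_CONCENTRATIONS[name][1],
            nymph_mean=hist["nymph"][0],
            nymph_sd=hist["nymph"][1] * sqrt_n,
            adult_longevity_mean=hist["longevity"][0],
            adult_longevity_sd=hist["longevity"][1] * sqrt_n,
            repro_days_mean=hist["repro_days"][0],
            repro_days_sd=hist["repro_days"][1] * sqrt_n,
            fecundity_mean=hist["fecundity"][0],
            fecundity_sd=hist["fecundity"][1] * sqrt_n,
            preadult_survival=min(1.0, survival),
            epg=_default_epg(relative),
            carrying_capacity=400.0 * relative,
            initial_density=5.0 * relative,
        )
        profiles[name].validate()
    return profiles


def _profile_to_dict(profile: TreatmentProfile) -> dict:
    data = asdict(profile)
    data["epg"] = {
        "sojourn_means": dict(profile.epg.sojourn_means),
        "transitions": {s: dict(w) for s, w in profile.epg.transitions.items()},
        "min_sojourn": profile.epg.min_sojourn,
    }
    return data


def dump_profiles(profiles: Mapping[str, TreatmentProfile], path) -> None:
    """Write profiles to a nested key-value (YAML) config file."""
    payload = {name: _profile_to_dict(p) for name, p in profiles.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_profiles(path) -> dict[str, TreatmentProfile]:
    """Read profiles from a config file written by :func:`dump_profiles`."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    profiles = {}
    for name, data in payload.items():
        epg = data.pop("epg")
        profile = TreatmentProfile(epg=EpgRates(**epg), **data)
        profile.validate()
        profiles[name] = profile
    return profiles
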