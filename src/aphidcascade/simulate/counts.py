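"""Negative-binomial count-series generator around a rise-then-decline curve.

The latent per-plant expectation follows logistic growth from the
initial infestation density toward the treatment's carrying capacity,
then decays multiplicatively after ``decline_day`` (host-quality
deterioration late in the experiment).  Observed counts are
negative-binomial draws around the latent curve with dispersion
``nb_dispersion`` (variance mu + mu^2/k; the Poisson limit as k grows).
Treatment curves are amplitude-scaled copies of the control curve, so
the population percent-of-control mean abundance equals the calibrated
ratio exactly.
"""

from __future__ import annotations

import numpy as np

from aphidcascade.abundance import DEFAULT_SURVEY_DAYS, SurveySeries
from aphidcascade.profiles import ProfileError, TreatmentProfile

__all__ = ["latent_curve", "gen_population_series"]


def latent_curve(profile: TreatmentProfile, days) -> np.ndarray:
    """Expected aphids per plant on each survey day."""
    days = np.asarray(days, dtype=float)
    K = profile.carrying_capacity
    N0 = profile.initial_density
    g = profile.growth_rate
    rise = K / (1.0 + (K / N0 - 1.0) * np.exp(-g * days))
    at_decline = K / (1.0 + (K / N0 - 1.0) * np.exp(-g * profile.decline_day))
    fall = at_decline * np.exp(-profile.decline_rate * (days - profile.decline_day))
    return np.where(days <= profile.decline_day, rise, fall)


def gen_population_series(
    profile: TreatmentProfile,
    n_reps: int = 15,
    seed: int | None = None,
    days: tuple[int, ...] = DEFAULT_SURVEY_DAYS,
) -> SurveySeries:
    """Simulate ``n_reps`` replicate count series for one treatment."""
    if n_reps < 1:
        raise ProfileError("n_reps must be >= 1")
    profile.validate()
    rng = np.random.default_rng(seed)
    mu = latent_curve(profile, days)
    k = profile.nb_dispersion
    # NB(mean mu, dispersion k) == numpy negative_binomial(n=k, p=k/(k+mu))
    p = k / (k + mu)
    counts = rng.negative_binomial(k, p[None, :].repeat(n_reps, axis=0)).astype(float)
    return SurveySeries(treatment=profile.name, days=tuple(days), counts=counts)
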