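"""Age-stage, two-sex life table analysis for parthenogenetic aphid cohorts.

The framework tracks a birth cohort jointly by age ``x`` (days, age 0 =
day of birth) and developmental stage ``j`` (here the pooled stage set
``nymph``/``adult``).  From per-individual daily records it builds

* ``s_xj`` — probability that a newborn is alive and in stage ``j`` at age
  ``x`` (age-stage survival),
* ``f_xj`` — mean offspring laid at age ``x`` per individual in stage ``j``,
* ``l_x = sum_j s_xj`` — age-specific survival,
* ``m_x = sum_j s_xj f_xj / sum_j s_xj`` — age-specific fecundity,

and from them the population growth parameters

* net reproductive rate ``R0 = sum_x l_x m_x``,
* intrinsic rate of increase ``r`` solving the Euler-Lotka equation
  ``sum_x exp(-r (x+1)) l_x m_x = 1`` (the ``x+1`` exponent follows the
  age-indexing convention in which reproduction at age x is credited at
  the end of day x),
* finite rate of increase ``lambda`` solving the equivalent equation in
  ``lambda^-(x+1)`` over ``sum_j f_xj s_xj`` (contract: equals ``exp(r)``),
* mean generation time ``T = ln(R0) / r``.

Because cotton aphids reproduce parthenogenetically the cohort is
all-female; the two-sex bookkeeping degenerates gracefully, with pre-adult
deaths entering ``s_xj`` as zero-fecundity survival mass rather than being
discarded.

Standard errors are bootstrap SDs over individual-level resamples, the
convention of the dedicated two-sex life-table software this module
re-implements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "STAGES",
    "IndividualRecord",
    "CohortSchedule",
    "LifeTableParams",
    "LifeTableError",
    "NoReproductionError",
    "build_schedule",
    "net_reproductive_rate",
    "intrinsic_rate",
    "finite_rate",
    "mean_generation_time",
    "bootstrap_lifetable",
    "cohort_summary",
    "read_cohort_csv",
    "write_cohort_csv",
    "parameter_table",
]

STAGES = ("nymph", "adult")

_RESIDUAL_TOL = 1e-10


class LifeTableError(ValueError):
    """Raised for invalid cohorts or schedules."""


class NoReproductionError(LifeTableError):
    """Raised when R0 = 0 and the growth rate is undefined."""


@dataclass(frozen=True)
class IndividualRecord:
    """One aphid's daily history from birth to death.

    ``stages[x]`` is the stage occupied at age ``x`` and ``offspring[x]``
    the offspring laid that day; both run from age 0 to the age of the
    last day alive (``death_age``).
    """

    id: str
    treatment: str
    stages: tuple[str, ...]
    offspring: tuple[int, ...]

    def __post_init__(self):
        if len(self.stages) == 0:
            raise LifeTableError(f"individual {self.id!r} has an empty history")
        if len(self.stages) != len(self.offspring):
            raise LifeTableError(f"individual {self.id!r}: stage/offspring length mismatch")
        seen_adult = False
        for x, stage in enumerate(self.stages):
            if stage not in STAGES:
                raise LifeTableError(f"individual {self.id!r}: unknown stage {stage!r}")
            if stage == "adult":
                seen_adult = True
            elif seen_adult:
                raise LifeTableError(f"individual {self.id!r}: stage reverts to nymph at age {x}")
            if self.offspring[x] < 0:
                raise LifeTableError(f"individual {self.id!r}: negative offspring at age {x}")
            if self.offspring[x] > 0 and stage != "adult":
                raise LifeTableError(
                    f"individual {self.id!r}: offspring recorded in stage {stage!r} at age {x}"
                )

    @property
    def death_age(self) -> int:
        """Age of the last day alive."""
        return len(self.stages) - 1

    @property
    def adult_molt_age(self) -> int | None:
        """Age at the adult molt (the nymph period), or None if never adult."""
        for x, stage in enumerate(self.stages):
            if stage == "adult":
                return x
        return None


@dataclass(frozen=True)
class CohortSchedule:
    """Age x stage survival and fecundity schedules of one cohort."""

    n: int
    stages: tuple[str, ...]
    s_xj: np.ndarray  # (ages, stages) survival probabilities
    f_xj: np.ndarray  # (ages, stages) mean offspring per stage-j individual

    def __post_init__(self):
        s, f = self.s_xj, self.f_xj
        if s.shape != f.shape or s.ndim != 2 or s.shape[1] != len(self.stages):
            raise LifeTableError("s_xj/f_xj shape mismatch")
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise LifeTableError("s_xj outside [0, 1]")
        if np.any(f < 0):
            raise LifeTableError("f_xj must be >= 0")
        lx = s.sum(axis=1)
        if abs(lx[0] - 1.0) > 1e-12:
            raise LifeTableError("l_0 must equal 1")
        if np.any(np.diff(lx) > 1e-12):
            raise LifeTableError("l_x must be non-increasing")

    @property
    def l_x(self) -> np.ndarray:
        """Age-specific survival, l_x = sum_j s_xj."""
        return self.s_xj.sum(axis=1)

    @property
    def m_x(self) -> np.ndarray:
        """Age-specific fecundity, m_x = sum_j s_xj f_xj / sum_j s_xj."""
        lx = self.l_x
        phi = self.net_fecundity
        with np.errstate(invalid="ignore", divide="ignore"):
            mx = np.where(lx > 0, phi / np.where(lx > 0, lx, 1.0), 0.0)
        return mx

    @property
    def net_fecundity(self) -> np.ndarray:
        """Expected offspring per newborn at each age: l_x * m_x = sum_j s_xj f_xj."""
        return (self.s_xj * self.f_xj).sum(axis=1)


@dataclass(frozen=True)
class LifeTableParams:
    """Point estimates and bootstrap SEs of the growth parameters."""

    r: float
    lam: float
    R0: float
    T: float
    se_r: float = 0.0
    se_lambda: float = 0.0
    se_R0: float = 0.0
    se_T: float = 0.0
    n_bootstrap: int = 0
    n_skipped: int = 0

    def __post_init__(self):
        if self.R0 < 0:
            raise LifeTableError("R0 must be >= 0")
        if abs(self.lam - np.exp(self.r)) > 1e-6 * max(1.0, self.lam):
            raise LifeTableError("lambda != exp(r)")
        if self.R0 > 0 and self.r != 0 and abs(self.T * self.r - np.log(self.R0)) > 1e-8:
            raise LifeTableError("T * r != ln(R0)")


def build_schedule(records: list[IndividualRecord], stages: tuple[str, ...] = STAGES) -> CohortSchedule:
    """Tally per-individual histories into age-stage schedules.

    ``s_xj`` counts individuals alive in stage j at age x over the cohort
    size n; ``f_xj`` divides the day's offspring laid by stage-j
    individuals by that head count (0 where nobody occupies the cell).
    """
    if not records:
        raise LifeTableError("empty cohort")
    n = len(records)
    n_ages = max(rec.death_age for rec in records) + 1
    stage_index = {s: j for j, s in enumerate(stages)}
    counts = np.zeros((n_ages, len(stages)))
    births = np.zeros((n_ages, len(stages)))
    for rec in records:
        for x, (stage, off) in enumerate(zip(rec.stages, rec.offspring)):
            try:
                j = stage_index[stage]
            except KeyError:
                raise LifeTableError(f"stage {stage!r} not in stage set {stages}") from None
            counts[x, j] += 1
            births[x, j] += off
    with np.errstate(invalid="ignore", divide="ignore"):
        f_xj = np.where(counts > 0, births / np.where(counts > 0, counts, 1.0), 0.0)
    return CohortSchedule(n=n, stages=tuple(stages), s_xj=counts / n, f_xj=f_xj)


def net_reproductive_rate(schedule: CohortSchedule) -> float:
    """R0 = sum_x l_x m_x, the expected lifetime offspring per newborn.

    Equals total cohort offspring / n exactly, including cohorts with
    pre-adult deaths (they contribute survival mass but no offspring).
    """
    return float(schedule.net_fecundity.sum())


def _euler_root(phi: np.ndarray, transform) -> float:
    """Solve sum_x transform(rho, x+1) * phi_x = 1 by bracketing + brentq.

    ``transform(rho, t)`` must be strictly decreasing in rho for the sum
    to be monotone; the bracket [-5, 5] (per day) is widened automatically.
    """
    ages = np.arange(1, len(phi) + 1, dtype=float)
    mask = phi > 0
    phi = phi[mask]
    ages = ages[mask]

    def f(rho: float) -> float:
        return float(transform(rho, ages) @ phi - 1.0)

    lo, hi = -5.0, 5.0
    for _ in range(60):
        if f(lo) > 0:
            break
        lo *= 2.0
    for _ in range(60):
        if f(hi) < 0:
            break
        hi *= 2.0
    root = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=300)
    if abs(f(root)) > _RESIDUAL_TOL:
        raise LifeTableError(f"Euler-Lotka residual {f(root):.2e} exceeds {_RESIDUAL_TOL:g}")
    return float(root)


def intrinsic_rate(schedule: CohortSchedule) -> float:
    """Intrinsic rate of increase r: sum_x exp(-r (x+1)) l_x m_x = 1.

    The left side is strictly decreasing in r, so the real root is unique;
    sign(r) = sign(ln R0).  Raises :class:`NoReproductionError` if R0 = 0.
    """
    phi = schedule.net_fecundity
    if phi.sum() <= 0:
        raise NoReproductionError("R0 = 0: intrinsic rate undefined")
    return _euler_root(phi, lambda r, t: np.exp(-r * t))


def finite_rate(schedule: CohortSchedule) -> float:
    """Finite rate of increase lambda: sum_x lambda^-(x+1) sum_j f_xj s_xj = 1.

    Solved independently of :func:`intrinsic_rate` (a root search in
    lambda rather than r); the two agree through lambda = exp(r).
    """
    phi = (schedule.f_xj * schedule.s_xj).sum(axis=1)
    if phi.sum() <= 0:
        raise NoReproductionError("R0 = 0: finite rate undefined")
    ages = np.arange(1, len(phi) + 1, dtype=float)
    mask = phi > 0
    phi, ages = phi[mask], ages[mask]

    def f(lam: float) -> float:
        return float(np.power(lam, -ages) @ phi - 1.0)

    lo, hi = np.exp(-5.0), np.exp(5.0)
    for _ in range(60):
        if f(lo) > 0:
            break
        lo /= 2.0
    for _ in range(60):
        if f(hi) < 0:
            break
        hi *= 2.0
    root = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=300)
    if abs(f(root)) > _RESIDUAL_TOL:
        raise LifeTableError(f"Euler-Lotka residual {f(root):.2e} exceeds {_RESIDUAL_TOL:g}")
    return float(root)


def mean_generation_time(R0: float, r: float) -> float:
    """Mean generation time T = ln(R0) / r, in days."""
    if R0 <= 0:
        raise NoReproductionError("R0 = 0: generation time undefined")
    if r == 0:
        raise LifeTableError("r = 0: generation time undefined")
    return float(np.log(R0) / r)


def _offspring_matrix(records: list[IndividualRecord]) -> np.ndarray:
    """Per-individual offspring-by-age matrix (n x ages), zero padded."""
    n_ages = max(rec.death_age for rec in records) + 1
    out = np.zeros((len(records), n_ages))
    for i, rec in enumerate(records):
        out[i, : len(rec.offspring)] = rec.offspring
    return out


def _params_from_phi(phi: np.ndarray) -> tuple[float, float, float, float]:
    R0 = float(phi.sum())
    r = _euler_root(phi, lambda r, t: np.exp(-r * t))
    lam = float(np.exp(r))
    T = float(np.log(R0) / r) if r != 0 else float("nan")
    return r, lam, R0, T


def bootstrap_lifetable(
    records: list[IndividualRecord], B: int = 2000, seed: int | None = None
) -> LifeTableParams:
    """Point estimates from the full cohort plus bootstrap SEs.

    Resamples n individuals with replacement B times and recomputes
    (r, lambda, R0, T) per resample; the SE is the SD across resamples.
    Resamples with R0 = 0 carry undefined parameters and are skipped, with
    the skip count recorded.  Within resamples lambda is evaluated as
    exp(r); the full-cohort point estimate is solved independently from
    the lambda-form equation.
    """
    if B < 2:
        raise LifeTableError("B must be >= 2")
    if not records:
        raise LifeTableError("empty cohort")
    schedule = build_schedule(records)
    if net_reproductive_rate(schedule) <= 0:
        raise NoReproductionError("cohort has zero total offspring")
    r = intrinsic_rate(schedule)
    lam = finite_rate(schedule)
    R0 = net_reproductive_rate(schedule)
    T = mean_generation_time(R0, r)

    rng = np.random.default_rng(seed)
    O = _offspring_matrix(records)
    n = len(records)
    draws = np.empty((B, 4))
    kept = 0
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        phi = O[idx].mean(axis=0)
        if phi.sum() <= 0:
            skipped += 1
            continue
        draws[kept] = _params_from_phi(phi)
        kept += 1
    if kept < 2:
        raise LifeTableError("fewer than 2 bootstrap resamples with reproduction")
    sds = draws[:kept].std(axis=0, ddof=1)
    return LifeTableParams(
        r=r, lam=lam, R0=R0, T=T,
        se_r=float(sds[0]), se_lambda=float(sds[1]), se_R0=float(sds[2]), se_T=float(sds[3]),
        n_bootstrap=kept, n_skipped=skipped,
    )


def cohort_summary(records: list[IndividualRecord]) -> pd.DataFrame:
    """Per-treatment mean and SE of the four cohort life-history traits.

    nymph period = age at the adult molt; adult longevity = days alive as
    an adult; reproductive days = number of days with >= 1 offspring;
    fecundity = lifetime offspring total.  Each trait is averaged only
    over individuals for which it is defined (the adult-based traits over
    individuals reaching adulthood); a cohort with no adults reports NaN
    for those traits with ``n_adult`` = 0.  SE = sd / sqrt(n) with the
    n-1 denominator; a single defined individual gives SE = NaN.
    """
    if not records:
        raise LifeTableError("empty cohort")
    rows = []
    for rec in records:
        molt = rec.adult_molt_age
        rows.append({
            "treatment": rec.treatment,
            "nymph_period": molt if molt is not None else np.nan,
            "adult_longevity": (rec.death_age - molt + 1) if molt is not None else np.nan,
            "reproductive_days": sum(1 for o in rec.offspring if o > 0) if molt is not None else np.nan,
            "fecundity": sum(rec.offspring) if molt is not None else np.nan,
        })
    df = pd.DataFrame(rows)
    out = {}
    grouped = df.groupby("treatment", sort=False)
    for trait in ("nymph_period", "adult_longevity", "reproductive_days", "fecundity"):
        out[f"{trait}_mean"] = grouped[trait].mean()
        out[f"{trait}_se"] = grouped[trait].sem()
    summary = pd.DataFrame(out)
    summary["n"] = grouped.size()
    summary["n_adult"] = grouped["nymph_period"].count()
    return summary


def parameter_table(
    cohorts: dict[str, list[IndividualRecord]], B: int = 2000, seed: int | None = None
) -> pd.DataFrame:
    """Per-treatment growth-parameter table (point estimates +/- bootstrap SE)."""
    seq = np.random.SeedSequence(seed)
    rows = []
    for (treatment, records), child in zip(cohorts.items(), seq.spawn(len(cohorts))):
        p = bootstrap_lifetable(records, B=B, seed=child.generate_state(1)[0] % (2**31))
        rows.append({
            "treatment": treatment,
            "r": p.r, "se_r": p.se_r,
            "lambda": p.lam, "se_lambda": p.se_lambda,
            "R0": p.R0, "se_R0": p.se_R0,
            "T": p.T, "se_T": p.se_T,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV dialect: one row per individual-day, columns
# individual_id, treatment, day, stage, offspring.  Death is encoded by the
# absence of later rows; an optional trailing row with stage == "dead" and
# offspring 0 is accepted and ignored on read.

def write_cohort_csv(records: list[IndividualRecord], path, died_flag: bool = False) -> None:
    rows = []
    for rec in records:
        for x, (stage, off) in enumerate(zip(rec.stages, rec.offspring)):
            rows.append((rec.id, rec.treatment, x, stage, off))
        if died_flag:
            rows.append((rec.id, rec.treatment, rec.death_age + 1, "dead", 0))
    pd.DataFrame(rows, columns=["individual_id", "treatment", "day", "stage", "offspring"]).to_csv(
        path, index=False
    )


def read_cohort_csv(path) -> list[IndividualRecord]:
    df = pd.read_csv(path)
    required = {"individual_id", "treatment", "day", "stage", "offspring"}
    missing = required - set(df.columns)
    if missing:
        raise LifeTableError(f"cohort CSV missing columns: {sorted(missing)}")
    records = []
    for (ind, treatment), grp in df.groupby(["individual_id", "treatment"], sort=False):
        grp = grp.sort_values("day")
        grp = grp[grp["stage"] != "dead"]
        days = grp["day"].to_numpy()
        if len(days) == 0 or days[0] != 0 or np.any(np.diff(days) != 1):
            raise LifeTableError(f"individual {ind!r}: days must run 0,1,2,... without gaps")
        records.append(
            IndividualRecord(
                id=str(ind),
                treatment=str(treatment),
                stages=tuple(grp["stage"]),
                offspring=tuple(int(o) for o in grp["offspring"]),
            )
        )
    return records
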