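"""Eligibility-and-uptake arithmetic sizing the two screening cohorts.

Counts are expected persons.  Every published milestone is a product or sum
of census inputs with one rounding rule: nearest integer, ties to even
(the unique simple rule consistent with all four printed milestones).
Rounding is done in exact rational arithmetic so that ties are genuine ties
rather than float artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction


class DomainError(ValueError):
    pass


def _as_fraction(x: float | int | str | Fraction) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    # str(float) round-trips the decimal literal the config stored
    return Fraction(str(x))


def _round_half_even(x: Fraction) -> int:
    return round(x)  # round() on Fraction is exact banker's rounding


def eligible_smokers(current_smokers: int, ex_smokers: int) -> int:
    """Smoking-history cohort: current plus ex heavy smokers."""
    if current_smokers < 0 or ex_smokers < 0:
        raise DomainError("smoker counts must be nonnegative")
    return int(current_smokers) + int(ex_smokers)


def eligible_nonsmokers(nonsmoking_population: int, high_risk_fraction: float) -> int:
    """Risk-factor cohort: the high-risk share of the never/ex-smoking pool."""
    f = _as_fraction(high_risk_fraction)
    if not (0 <= f <= 1):
        raise DomainError(f"high_risk_fraction {high_risk_fraction!r} outside [0, 1]")
    if nonsmoking_population < 0:
        raise DomainError("population must be nonnegative")
    return _round_half_even(_as_fraction(nonsmoking_population) * f)


def screened_population(eligible_total: int, uptake: float) -> int:
    """Screened persons after applying the uptake rate."""
    u = _as_fraction(uptake)
    if not (0 <= u <= 1):
        raise DomainError(f"uptake {uptake!r} outside [0, 1]")
    if eligible_total < 0:
        raise DomainError("eligible count must be nonnegative")
    return _round_half_even(_as_fraction(eligible_total) * u)


def population_share(count: int, total: int) -> float:
    """Percent of the total population, rounded to 2 decimals (nearest)."""
    if total <= 0:
        raise DomainError("total population must be positive")
    return float(round(Fraction(100) * Fraction(count, total), 2))


@dataclass
class PopulationFunnel:
    total_population: int
    eligible_smokers: int
    eligible_nonsmokers: int
    eligible_total: int
    screened_total: int
    screened_by_cohort: dict[str, int]
    eligible_share_of_population: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "total_population": self.total_population,
            "eligible_smokers": self.eligible_smokers,
            "eligible_nonsmokers": self.eligible_nonsmokers,
            "eligible_total": self.eligible_total,
            "screened_total": self.screened_total,
            "screened_by_cohort": dict(self.screened_by_cohort),
            "eligible_share_of_population": dict(self.eligible_share_of_population),
        }


def build_funnel(
    total_population: int,
    current_smokers: int,
    ex_smokers: int,
    nonsmoking_pool: int,
    high_risk_fraction: float,
    uptake: float,
) -> PopulationFunnel:
    """One call chain reproducing all published cohort-size milestones.

    Uptake is applied to the combined eligible total for the headline
    screened count, and separately per cohort for arm sizing; the per-cohort
    sum may differ from the combined figure by at most one person (rounding
    happens at each milestone).
    """
    n_smoke = eligible_smokers(current_smokers, ex_smokers)
    n_nonsmoke = eligible_nonsmokers(nonsmoking_pool, high_risk_fraction)
    n_total = n_smoke + n_nonsmoke
    screened = screened_population(n_total, uptake)
    by_cohort = {
        "smoking": screened_population(n_smoke, uptake),
        "nonsmoking": screened_population(n_nonsmoke, uptake),
    }
    assert abs(sum(by_cohort.values()) - screened) <= 1, "per-cohort rounding drifted by more than one person"
    return PopulationFunnel(
        total_population=total_population,
        eligible_smokers=n_smoke,
        eligible_nonsmokers=n_nonsmoke,
        eligible_total=n_total,
        screened_total=screened,
        screened_by_cohort=by_cohort,
        eligible_share_of_population={
            "smoking": population_share(n_smoke, total_population),
            "nonsmoking": population_share(n_nonsmoke, total_population),
        },
    )


def fixture_funnel(smoking_params, nonsmoking_params) -> PopulationFunnel:
    """Funnel from the two cohort parameter packs."""
    epi_s = smoking_params.epidemiology
    epi_n = nonsmoking_params.epidemiology
    return build_funnel(
        total_population=int(epi_s.total_population),
        current_smokers=int(epi_s.eligible_current_smokers),
        ex_smokers=int(epi_s.eligible_ex_smokers),
        nonsmoking_pool=int(epi_n.nonsmoking_pool),
        high_risk_fraction=epi_n.nonsmoker_high_risk_fraction,
        uptake=epi_s.uptake,
    )
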