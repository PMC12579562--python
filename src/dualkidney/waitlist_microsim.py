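"""Discrete-time microsimulation of the kidney transplant waitlist.

A closed cohort of candidates is followed annually across three states —
waitlist, transplanted, death — under yearly transition probabilities.
Transplanted and death are absorbing. Two allocation pathways are compared:
Path 1 (current practice) uses the schedule's transplant probabilities as
given; Path 2 (all dual transplants performed as singles) inflates each
year's transplant probability by that year's dual-transplant fraction,
``p_tx' = min(1 - p_death, p_tx * (1 + dual_fraction))`` — each converted
dual frees exactly one additional organ-equivalent transplant.

Each candidate-year consumes a single uniform draw checked against
cumulative thresholds in the order death, transplant, remain; with common
random numbers the two pathways share the draws, which couples them so a
candidate transplanted under Path 1 is transplanted no later under Path 2
and waitlist deaths can only decrease.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_registry import ConfigurationError, WaitlistSchedule

PATHWAYS = ("path1_current", "path2_all_single")
_WAIT, _TX, _DEAD = 0, 1, 2


@dataclass
class SimConfig:
    schedule: WaitlistSchedule
    n_candidates: int = 100_000
    pathway: str = "path1_current"
    seed: int = 0
    common_random_numbers: bool = True
    n_years: int | None = None

    def validate(self) -> None:
        if self.n_candidates <= 0:
            raise ConfigurationError("n_candidates must be positive")
        if self.pathway not in PATHWAYS:
            raise ConfigurationError(f"unknown pathway {self.pathway!r}")
        if self.n_years is not None and self.n_years != len(self.schedule):
            raise ConfigurationError("n_years must equal the schedule length")
        self.schedule.validate()


@dataclass
class SimResult:
    pathway: str
    per_year: pd.DataFrame  # year, n_waitlist, n_transplanted_cum, n_dead_cum
    total_waitlist_deaths: int
    total_transplants: int
    n_candidates: int
    transplant_year: np.ndarray = field(default=None, repr=False)
    death_year: np.ndarray = field(default=None, repr=False)

    def validate(self) -> None:
        tot = (self.per_year["n_waitlist"] + self.per_year["n_transplanted_cum"]
               + self.per_year["n_dead_cum"])
        assert (tot == self.n_candidates).all(), "state conservation violated"
        assert self.per_year["n_transplanted_cum"].is_monotonic_increasing
        assert self.per_year["n_dead_cum"].is_monotonic_increasing


def effective_p_transplant(schedule: WaitlistSchedule, pathway: str) -> np.ndarray:
    if pathway == "path1_current":
        return schedule.p_transplant.copy()
    p = schedule.p_transplant * (1.0 + schedule.dual_fraction)
    return np.minimum(1.0 - schedule.p_death, p)


def run_microsim(config: SimConfig, _uniforms: np.ndarray | None = None) -> SimResult:
    """Simulate one pathway; deterministic given the seed.

    ``_uniforms`` lets ``compare_pathways`` supply one shared draw matrix
    (common random numbers) to both pathways.
    """
    config.validate()
    sched = config.schedule
    n, ny = config.n_candidates, len(sched)
    if _uniforms is None:
        _uniforms = np.random.default_rng(config.seed).random((ny, n))
    p_tx = effective_p_transplant(sched, config.pathway)
    if ((p_tx + sched.p_death) > 1.0 + 1e-12).any():
        raise ConfigurationError("adjusted probabilities exceed 1")

    state = np.full(n, _WAIT, dtype=np.int8)
    tx_year = np.full(n, -1, dtype=np.int32)
    death_year = np.full(n, -1, dtype=np.int32)
    rows = []
    for y in range(ny):
        u = _uniforms[y]
        on_list = state == _WAIT
        dies = on_list & (u < sched.p_death[y])
        transplanted = on_list & ~dies & (u < sched.p_death[y] + p_tx[y])
        state[dies] = _DEAD
        state[transplanted] = _TX
        death_year[dies] = y
        tx_year[transplanted] = y
        rows.append({
            "year": sched.years[y],
            "n_waitlist": int((state == _WAIT).sum()),
            "n_transplanted_cum": int((state == _TX).sum()),
            "n_dead_cum": int((state == _DEAD).sum()),
        })
    per_year = pd.DataFrame(rows)
    result = SimResult(
        pathway=config.pathway,
        per_year=per_year,
        total_waitlist_deaths=int((state == _DEAD).sum()),
        total_transplants=int((state == _TX).sum()),
        n_candidates=n,
        transplant_year=tx_year,
        death_year=death_year,
    )
    result.validate()
    return result


@dataclass
class PathwayComparison:
    path1: SimResult
    path2: SimResult
    relative_death_reduction: float  # percent
    additional_transplants: int
    undefined: bool = False


def compare_pathways(config: SimConfig) -> PathwayComparison:
    """Run both pathways (shared draws when common_random_numbers) and report
    the relative reduction in waitlist deaths under Path 2."""
    config.validate()
    uniforms = None
    if config.common_random_numbers:
        uniforms = np.random.default_rng(config.seed).random(
            (len(config.schedule), config.n_candidates))
    results = {}
    for pw in PATHWAYS:
        cfg = SimConfig(schedule=config.schedule, n_candidates=config.n_candidates,
                        pathway=pw, seed=config.seed,
                        common_random_numbers=config.common_random_numbers)
        results[pw] = run_microsim(cfg, _uniforms=uniforms)
    d1 = results["path1_current"].total_waitlist_deaths
    d2 = results["path2_all_single"].total_waitlist_deaths
    undefined = d1 == 0
    reduction = float("nan") if undefined else 100.0 * (d1 - d2) / d1
    return PathwayComparison(
        path1=results["path1_current"],
        path2=results["path2_all_single"],
        relative_death_reduction=reduction,
        additional_transplants=(results["path2_all_single"].total_transplants
                                - results["path1_current"].total_transplants),
        undefined=undefined,
    )


def expected_outcomes(schedule: WaitlistSchedule, pathway: str = "path1_current") -> dict:
    """Analytic Markov-chain expectations (per candidate) for a schedule:
    probability of waitlist death, transplant, and remaining listed."""
    p_tx = effective_p_transplant(schedule, pathway)
    p_death = schedule.p_death
    alive_on_list = 1.0
    e_death = e_tx = 0.0
    for y in range(len(schedule)):
        e_death += alive_on_list * p_death[y]
        e_tx += alive_on_list * p_tx[y]
        alive_on_list *= 1.0 - p_death[y] - p_tx[y]
    return {"p_waitlist_death": e_death, "p_transplant": e_tx,
            "p_still_listed": alive_on_list}
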