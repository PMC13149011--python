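"""Discrete-time individual-based S -> E -> {A, I} -> S epidemic simulator.

The model tracks, for every agent in a closed population of N individuals,
an epidemiological state (susceptible, latently exposed, asymptomatically
or symptomatically infectious), a scalar correlate of protection (COP)
``X`` in [0, 1], and a fixed baseline risk multiplier ``R`` in {1, 2}.

Per-day dynamics
----------------
* A susceptible with COP ``X`` is infected with probability
  ``gamma * (1 - psi(X)) * (I + A) * R`` (clipped at 1), where
  ``gamma = R0 / (N * t_infectious)`` and ``I + A`` is the current number
  of infectious agents — a discrete-time hazard with leaky, partial
  protection.
* Latency lasts ``t_latent`` days, after which the agent becomes
  symptomatic with probability ``alpha`` (drawn once, at infection) and
  asymptomatic otherwise; infectiousness lasts ``t_infectious`` days.
* On recovery the agent returns to the susceptible pool with a boosted
  COP: 0.75 after a first-ever exposure, 1.00 after any later one.
* Susceptibles wane linearly at ``w`` COP units per day (floored at 0);
  exposed and infectious agents hold their COP frozen until the recovery
  boost.
* Every ``vacc_interval`` days a uniform-random ``vacc_fraction`` of the
  eligible population (not symptomatically infectious, and at least
  ``t_revaccination`` days since their last dose) is vaccinated; a dose
  applies the same first/subsequent boost rule.

The population is stored as a struct of numpy arrays (one entry per
agent), which keeps a 600-day, 50,000-agent run well under a second or
two — the simulation is the inner loop of every replicate study here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


import numpy as np
import pandas as pd

from .protection import ProtectionSpec, psi

__all__ = [
    "STATE_S",
    "STATE_E",
    "STATE_A",
    "STATE_I",
    "SimConfig",
    "Population",
    "SimHistory",
    "transmission_coefficient",
    "infection_probability",
    "step_day",
    "vaccinate",
    "run_simulation",
]

STATE_S, STATE_E, STATE_A, STATE_I = 0, 1, 2, 3
_NO_DOSE = -(10**6)  # sentinel: never vaccinated

BOOST_FIRST = 0.75
BOOST_SUBSEQUENT = 1.00


@dataclass(frozen=True)
class SimConfig:
    """All simulation parameters.

    Defaults are the base (scenario 1) parameterization: a closed
    population of 50,000, R0 = 2, 5-day latency, 7-day infectious period,
    waning at 0.01 COP units/day, rolling vaccination of 0.5% of
    eligibles every 15 days, and no high-risk group.  Scenario 2 sets
    ``p_high_risk = 0.2`` (high-risk agents face a doubled hazard).
    """

    N: int = 50_000
    t_latent: int = 5
    t_infectious: int = 7
    t_revaccination: int = 56
    alpha: float = 1.0 / 3.0
    R0: float = 2.0
    w: float = 0.01
    p_high_risk: float = 0.0
    horizon: int = 600
    vacc_interval: int = 15
    vacc_fraction: float = 0.005
    initial_naive_S: int = 48_950
    initial_prior_exposure_S: int = 1_000
    initial_E: int = 25
    initial_infectious: int = 25
    record_interval: int = 10

    def __post_init__(self) -> None:
        total = (
            self.initial_naive_S
            + self.initial_prior_exposure_S
            + self.initial_E
            + self.initial_infectious
        )
        if total != self.N:
            raise ValueError(
                f"initial compartments sum to {total}, expected N={self.N}"
            )
        if self.N <= 0 or self.t_infectious <= 0:
            raise ValueError("N and t_infectious must be positive")
        if not 0 <= self.p_high_risk <= 1:
            raise ValueError("p_high_risk must lie in [0, 1]")

    @property
    def gamma(self) -> float:
        return transmission_coefficient(self)

    def vaccination_days(self) -> np.ndarray:
        """Round days 1, 1 + interval, ... within the horizon."""
        return np.arange(1, self.horizon + 1, self.vacc_interval)

    def to_dict(self) -> dict:
        return asdict(self)


def transmission_coefficient(config: SimConfig) -> float:
    """Per-contact-day transmission rate gamma = R0 / (N * t_infectious)."""
    return config.R0 / (config.N * config.t_infectious)


@dataclass
class Population:
    """Struct-of-arrays agent population; one array entry per agent."""

    state: np.ndarray  # int8, STATE_* codes
    cop: np.ndarray  # float64 in [0, 1]
    risk: np.ndarray  # int8, 1 (low) or 2 (high)
    ever_exposed: np.ndarray  # bool: had a completed exposure (boost applied)
    stage_end: np.ndarray  # int32: day the current E or A/I stage ends
    symptomatic_fate: np.ndarray  # bool, drawn at infection
    last_dose_day: np.ndarray  # int32, _NO_DOSE if never dosed
    ever_dosed: np.ndarray  # bool
    ever_eligible: np.ndarray  # bool: was eligible at >=1 vaccination round

    @property
    def n(self) -> int:
        return self.state.size

    def counts(self) -> tuple[int, int, int, int]:
        c = np.bincount(self.state, minlength=4)
        return int(c[STATE_S]), int(c[STATE_E]), int(c[STATE_A]), int(c[STATE_I])


def _initial_population(config: SimConfig, rng: np.random.Generator) -> Population:
    n = config.N
    state = np.full(n, STATE_S, dtype=np.int8)
    cop = np.zeros(n)
    ever_exposed = np.zeros(n, dtype=bool)
    stage_end = np.zeros(n, dtype=np.int32)
    fate = np.zeros(n, dtype=bool)

    # layout: [naive S | prior-exposure S | E | infectious]
    i0 = config.initial_naive_S
    i1 = i0 + config.initial_prior_exposure_S
    i2 = i1 + config.initial_E
    cop[i0:i1] = BOOST_FIRST
    ever_exposed[i0:i1] = True

    state[i1:i2] = STATE_E
    stage_end[i1:i2] = config.t_latent
    fate[i1:i2] = rng.random(config.initial_E) < config.alpha

    # symptomatic seeds ~ Binomial(n_infectious, alpha); the remainder are
    # asymptomatic so the compartment total is conserved
    n_symp = rng.binomial(config.initial_infectious, config.alpha)
    state[i2 : i2 + n_symp] = STATE_I
    state[i2 + n_symp : n] = STATE_A
    stage_end[i2:n] = config.t_infectious

    risk = np.where(rng.random(n) < config.p_high_risk, 2, 1).astype(np.int8)

    return Population(
        state=state,
        cop=cop,
        risk=risk,
        ever_exposed=ever_exposed,
        stage_end=stage_end,
        symptomatic_fate=fate,
        last_dose_day=np.full(n, _NO_DOSE, dtype=np.int32),
        ever_dosed=np.zeros(n, dtype=bool),
        ever_eligible=np.zeros(n, dtype=bool),
    )


def infection_probability(
    cop,
    n_infectious: int,
    config: SimConfig,
    spec: ProtectionSpec | str = "linear",
    risk=1,
):
    """Per-day infection probability for susceptibles.

    min(1, gamma * (1 - psi(X)) * (I + A) * R); exactly 0 for a fully
    protected agent (X = 1 under any form) or when no one is infectious.
    """
    hazard = config.gamma * (1.0 - psi(cop, spec)) * n_infectious * np.asarray(risk)
    return np.minimum(hazard, 1.0)


def _apply_boost(pop: Population, idx: np.ndarray) -> None:
    """First-ever exposure boosts COP to 0.75, any subsequent one to 1.00."""
    pop.cop[idx] = np.where(pop.ever_exposed[idx], BOOST_SUBSEQUENT, BOOST_FIRST)
    pop.ever_exposed[idx] = True


def vaccinate(
    pop: Population, day: int, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Dose a uniform-random ``vacc_fraction`` of currently eligible agents.

    Eligible = not symptomatically infectious and at least
    ``t_revaccination`` days since the last dose.  Returns dosed indices.
    """
    eligible = (pop.state != STATE_I) & (
        day - pop.last_dose_day >= config.t_revaccination
    )
    pop.ever_eligible |= eligible
    elig_idx = np.flatnonzero(eligible)
    n_dose = int(round(config.vacc_fraction * elig_idx.size))
    if n_dose == 0:
        return np.empty(0, dtype=np.intp)
    dosed = rng.choice(elig_idx, size=n_dose, replace=False)
    # infected (E/A) recipients keep their antibody level frozen until the
    # recovery boost; only susceptibles see an immediate COP rise
    _apply_boost(pop, dosed[pop.state[dosed] == STATE_S])
    pop.last_dose_day[dosed] = day
    pop.ever_dosed[dosed] = True
    return dosed


def step_day(
    pop: Population,
    day: int,
    config: SimConfig,
    spec: ProtectionSpec | str,
    rng: np.random.Generator,
) -> dict:
    """Advance the population by one day (in place).

    Event order within the day: infection, latent progression, recovery
    with boost, waning of susceptibles, then vaccination (on round days).
    Returns the day's incident symptomatic cases (ids, their frozen COP,
    risk group) — these are the agents whose symptomatic infectious
    period begins today.
    """
    n_infectious = int(np.count_nonzero(pop.state >= STATE_A))

    # (a) infection of susceptibles
    s_idx = np.flatnonzero(pop.state == STATE_S)
    if n_infectious > 0 and s_idx.size > 0:
        p = infection_probability(
            pop.cop[s_idx], n_infectious, config, spec, pop.risk[s_idx]
        )
        new_inf = s_idx[rng.random(s_idx.size) < p]
        pop.state[new_inf] = STATE_E
        pop.stage_end[new_inf] = day + config.t_latent
        pop.symptomatic_fate[new_inf] = rng.random(new_inf.size) < config.alpha

    # (b) end of latency: E -> A or I per the fate drawn at infection
    due_e = np.flatnonzero((pop.state == STATE_E) & (pop.stage_end <= day))
    onset_i = due_e[pop.symptomatic_fate[due_e]]
    onset_a = due_e[~pop.symptomatic_fate[due_e]]
    pop.state[onset_i] = STATE_I
    pop.state[onset_a] = STATE_A
    pop.stage_end[due_e] = day + config.t_infectious
    incident = {
        "id": onset_i,
        "cop": pop.cop[onset_i].copy(),  # frozen since infection
        "risk": pop.risk[onset_i].copy(),
    }

    # (c) recovery back to S with the exposure boost
    due_r = np.flatnonzero((pop.state >= STATE_A) & (pop.stage_end <= day))
    pop.state[due_r] = STATE_S
    _apply_boost(pop, due_r)

    # (d) linear waning of all susceptibles; E/A/I hold COP frozen
    s_mask = pop.state == STATE_S
    pop.cop[s_mask] = np.maximum(pop.cop[s_mask] - config.w, 0.0)

    # (e) vaccination round
    if (day - 1) % config.vacc_interval == 0:
        vaccinate(pop, day, config, rng)

    return incident


@dataclass
class SimHistory:
    """Full record of one simulation run.

    ``counts`` holds per-day compartment sizes and incident symptomatic
    counts; ``cases`` the per-case log (day, agent id, COP frozen at
    infection, risk group); ``snapshots`` maps each recorded day to
    end-of-day ``(state, cop)`` arrays.  ``risk`` is static per agent.
    """

    config: SimConfig
    spec: ProtectionSpec
    counts: pd.DataFrame
    cases: pd.DataFrame
    snapshots: dict[int, tuple[np.ndarray, np.ndarray]]
    risk: np.ndarray
    ever_dosed: np.ndarray = field(repr=False, default=None)
    ever_eligible: np.ndarray = field(repr=False, default=None)

    def cases_on(self, day: int) -> pd.DataFrame:
        return self.cases[self.cases["day"] == day]

    def snapshot_frame(self, day: int) -> pd.DataFrame:
        """One recorded day as a (day, id, state, cop, risk) table."""
        state, cop = self.snapshots[day]
        return pd.DataFrame(
            {
                "day": day,
                "id": np.arange(state.size),
                "state": state,
                "cop": cop,
                "risk": self.risk,
            }
        )

    def vaccination_coverage(self) -> float:
        """Fraction of ever-eligible agents with at least one dose."""
        n_elig = int(np.count_nonzero(self.ever_eligible))
        if n_elig == 0:
            return 0.0
        return float(np.count_nonzero(self.ever_dosed & self.ever_eligible) / n_elig)

    def to_csv(self, counts_path, snapshot_path=None) -> None:
        self.counts.to_csv(counts_path, index=False)
        if snapshot_path is not None:
            pd.concat(
                [self.snapshot_frame(d) for d in sorted(self.snapshots)]
            ).to_csv(snapshot_path, index=False)


def run_simulation(
    config: SimConfig | None = None,
    spec: ProtectionSpec | str = "linear",
    rng: np.random.Generator | int | None = None,
) -> SimHistory:
    """Run one full epidemic and return its history.

    Population snapshots (state and COP of every agent) are recorded at
    the end of every ``record_interval``-th day; the incident symptomatic
    case log and compartment counts are recorded daily.
    """
    config = config or SimConfig()
    if isinstance(spec, str):
        spec = ProtectionSpec(spec)
    rng = np.random.default_rng(rng)

    pop = _initial_population(config, rng)

    days = np.arange(config.horizon + 1)
    count_rows = np.zeros((config.horizon + 1, 5), dtype=np.int64)
    count_rows[0, :4] = pop.counts()
    case_days: list[np.ndarray] = []
    case_ids: list[np.ndarray] = []
    case_cops: list[np.ndarray] = []
    case_risks: list[np.ndarray] = []
    snapshots: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    for day in range(1, config.horizon + 1):
        incident = step_day(pop, day, config, spec, rng)
        count_rows[day, :4] = pop.counts()
        count_rows[day, 4] = incident["id"].size
        if incident["id"].size:
            case_days.append(np.full(incident["id"].size, day, dtype=np.int32))
            case_ids.append(incident["id"])
            case_cops.append(incident["cop"])
            case_risks.append(incident["risk"])
        if day % config.record_interval == 0:
            snapshots[day] = (pop.state.copy(), pop.cop.copy())

    counts = pd.DataFrame(
        count_rows, columns=["S", "E", "A", "I", "incident_symptomatic"]
    )
    counts.insert(0, "day", days)

    if case_ids:
        cases = pd.DataFrame(
            {
                "day": np.concatenate(case_days),
                "id": np.concatenate(case_ids),
                "cop": np.concatenate(case_cops),
                "risk": np.concatenate(case_risks),
            }
        )
    else:
        cases = pd.DataFrame(
            {
                "day": np.empty(0, dtype=np.int32),
                "id": np.empty(0, dtype=np.intp),
                "cop": np.empty(0),
                "risk": np.empty(0, dtype=np.int8),
            }
        )

    return SimHistory(
        config=config,
        spec=spec,
        counts=counts,
        cases=cases,
        snapshots=snapshots,
        risk=pop.risk,
        ever_dosed=pop.ever_dosed,
        ever_eligible=pop.ever_eligible,
    )
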