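"""Daily-step simulation of preference learning over grades K-6.

Each agent is simulated for ``n_years`` blocks of ``days_per_year`` school
days (1260 steps at the defaults).  At the start of each grade-year one
healthy-situation probability gamma is drawn from the agent's desert status
and FFVP participation for that year.  Each school day the agent either
lands in the healthy-only situation (probability gamma) and consumes
healthy food, or faces a choice and picks healthy food with the Luce
probability; every healthy consumption applies one temporal-difference
update.  A daily servings count is drawn from the current preference via
the Poisson quantile map.

Random-stream discipline: each simulated day consumes exactly three
uniforms (situation, choice, servings) regardless of which branch is taken,
and each year consumes its gamma draw(s) first.  This makes the scalar
:func:`step_agent` and the batched :func:`simulate_agent` produce identical
results from the same stream, and lets every agent run on an independent
substream derived from the master seed so cohort results are independent of
iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import AgentRecord, N_GRADES
from .core import (
    EnvironmentParams,
    Palatability,
    PreferenceState,
    ServingModel,
    choice_prob,
    draw_gamma,
    draw_servings,
    poisson_quantile,
)

__all__ = [
    "SimulationConfig",
    "StepRecord",
    "Trajectory",
    "agent_rng",
    "step_agent",
    "simulate_agent",
    "simulate_cohort",
    "trajectories_to_frame",
    "trajectories_from_frame",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Schedule, environment, and recording options for a simulation run.

    Defaults follow the study schedule: 180 school days per year for 7
    academic years, i.e. 1260 steps per agent.  ``record_every`` thins the
    stored trajectory (the final step is always recorded).  ``gamma_per_day``
    switches the environment draw from once per agent-year (default; FFVP
    and desert status are yearly attributes) to an independent redraw each
    day.  ``end_servings_mode`` controls the end-of-study servings summary:
    ``"final_year_mean"`` (default) averages the daily draws of the last
    year, ``"single_draw"`` takes one draw at the final preference.
    """

    days_per_year: int = 180
    n_years: int = N_GRADES
    env: EnvironmentParams = field(default_factory=EnvironmentParams)
    serving_model: ServingModel = field(default_factory=ServingModel)
    palatability: Palatability = field(default_factory=Palatability)
    record_every: int = 10
    gamma_per_day: bool = False
    gamma_override: float | None = None
    end_servings_mode: str = "final_year_mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days_per_year < 1 or self.n_years < 1:
            raise ValueError("days_per_year and n_years must be >= 1")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.end_servings_mode not in ("final_year_mean", "single_draw"):
            raise ValueError(f"unknown end_servings_mode {self.end_servings_mode!r}")
        if self.gamma_override is not None and not 0 <= self.gamma_override <= 1:
            raise ValueError("gamma_override must be in [0, 1]")

    @property
    def total_steps(self) -> int:
        return self.days_per_year * self.n_years


@dataclass(frozen=True)
class StepRecord:
    """Outcome of a single simulated school day."""

    healthy_only: bool
    consumed_healthy: bool
    v_hat_H: float
    p_choice: float
    servings: int


@dataclass
class Trajectory:
    """Recorded path of one agent plus end-of-study summaries.

    ``step`` holds 1-based day indices (strictly increasing); ``v_hat_H``
    is the post-update valuation at the end of each recorded day and is
    non-decreasing.  ``mean_servings`` is the end-of-study servings summary
    under the configured mode.
    """

    agent_id: int
    step: np.ndarray
    v_hat_H: np.ndarray
    p_choice: np.ndarray
    healthy_only: np.ndarray
    consumed_healthy: np.ndarray
    servings: np.ndarray
    final_v: float
    final_p: float
    mean_servings: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "agent_id": self.agent_id,
                "step": self.step,
                "v_hat_H": self.v_hat_H,
                "p_choice": self.p_choice,
                "situation": np.where(self.healthy_only, "healthy_only", "choice"),
                "consumed_healthy": self.consumed_healthy.astype(int),
                "servings": self.servings,
            }
        )


def agent_rng(master_seed: int, agent_id: int) -> np.random.Generator:
    """Independent per-agent generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, agent_id]))


def step_agent(
    state: PreferenceState,
    gamma: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[PreferenceState, StepRecord]:
    """Simulate one school day for an agent in environment ``gamma``.

    With probability gamma the day is a healthy-only situation and healthy
    food is consumed; otherwise the agent faces a choice and consumes
    healthy food with the Luce probability.  Healthy consumption applies
    one temporal-difference update.  Three uniforms are consumed per call
    (situation, choice, servings) whatever the branch, so sequences of
    calls stay aligned with the batched simulator.
    """
    u_sit = rng.random()
    u_choice = rng.random()
    u_serv = rng.random()
    healthy_only = u_sit < gamma
    consumed = healthy_only or u_choice < choice_prob(state)
    if consumed:
        state = PreferenceState(
            v_hat_H=state.v_hat_H
            + state.alpha * (cfg.palatability.beta_H - state.v_hat_H),
            alpha=state.alpha,
        )
    v = state.v_hat_H
    # u = v*(1-U) lies in (0, v]; at v = 0 the quantile at 0 gives 0 servings
    servings = poisson_quantile(v * (1.0 - u_serv), cfg.serving_model.lam)
    return state, StepRecord(healthy_only, consumed, v, choice_prob(state), servings)


def _year_gammas(
    agent: AgentRecord, year: int, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Gamma value(s) for one agent-year: a length-1 array in the yearly
    mode, one value per day in the per-day mode."""
    if cfg.gamma_override is not None:
        n = cfg.days_per_year if cfg.gamma_per_day else 1
        return np.full(n, cfg.gamma_override)
    desert = agent.desert[year] == "1"
    ffvp = agent.exposure[year] == "1"
    n = cfg.days_per_year if cfg.gamma_per_day else 1
    return np.array([draw_gamma(desert, ffvp, cfg.env, rng) for _ in range(n)])


def simulate_agent(
    agent: AgentRecord,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Run one agent over the full K-6 schedule.

    The agent's exposure pattern and desert history must have exactly
    ``cfg.n_years`` digits.  If ``rng`` is omitted, the agent's own
    substream (master seed, agent_id) is used.
    """
    if len(agent.exposure) != cfg.n_years or len(agent.desert) != cfg.n_years:
        raise ValueError(
            f"exposure/desert history length must equal n_years={cfg.n_years}"
        )
    if rng is None:
        rng = agent_rng(cfg.seed, agent.agent_id)

    beta_H = cfg.palatability.beta_H
    alpha = agent.alpha
    lam = cfg.serving_model.lam
    days = cfg.days_per_year
    v = 0.0

    v_path = np.empty(cfg.total_steps)
    healthy_only = np.empty(cfg.total_steps, dtype=bool)
    consumed_path = np.empty(cfg.total_steps, dtype=bool)
    servings_path = np.empty(cfg.total_steps, dtype=np.int64)

    for year in range(cfg.n_years):
        gammas = _year_gammas(agent, year, cfg, rng)
        u = rng.random((days, 3))
        base = year * days
        for d in range(days):
            g = gammas[d] if gammas.size > 1 else gammas[0]
            sit = u[d, 0] < g
            consumed = sit or u[d, 1] < v / (1.0 + v)
            if consumed:
                v += alpha * (beta_H - v)
            i = base + d
            v_path[i] = v
            healthy_only[i] = sit
            consumed_path[i] = consumed
        v_year = v_path[base : base + days]
        u_serv = v_year * (1.0 - u[:, 2])  # (0, v] daily; exactly 0 while v = 0
        servings_path[base : base + days] = poisson_quantile(u_serv, lam)

    final_v = float(v_path[-1])
    final_p = final_v / (1.0 + final_v)
    if cfg.end_servings_mode == "final_year_mean":
        mean_servings = float(servings_path[-days:].mean())
    else:
        mean_servings = float(
            draw_servings(
                PreferenceState(v_hat_H=final_v, alpha=alpha), cfg.serving_model, rng
            )
        )

    keep = np.zeros(cfg.total_steps, dtype=bool)
    keep[cfg.record_every - 1 :: cfg.record_every] = True
    keep[-1] = True
    idx = np.flatnonzero(keep)
    p_path = v_path[idx] / (1.0 + v_path[idx])
    return Trajectory(
        agent_id=agent.agent_id,
        step=idx + 1,
        v_hat_H=v_path[idx],
        p_choice=p_path,
        healthy_only=healthy_only[idx],
        consumed_healthy=consumed_path[idx],
        servings=servings_path[idx],
        final_v=final_v,
        final_p=final_p,
        mean_servings=mean_servings,
    )


def simulate_cohort(
    cohort: list[AgentRecord],
    cfg: SimulationConfig,
    keep_trajectories: bool = True,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Simulate every agent on its own substream.

    Returns the per-agent trajectories (empty list when
    ``keep_trajectories`` is False, which saves memory on large cohorts)
    and a final-state table with one row per agent: final valuation, final
    choice probability, and the end-of-study servings summary.  Results do
    not depend on the order of ``cohort``.
    """
    trajectories: list[Trajectory] = []
    rows = []
    for agent in cohort:
        traj = simulate_agent(agent, cfg)
        rows.append(
            (
                agent.agent_id,
                agent.exposure,
                agent.desert,
                traj.final_v,
                traj.final_p,
                traj.mean_servings,
            )
        )
        if keep_trajectories:
            trajectories.append(traj)
    final = pd.DataFrame(
        rows,
        columns=[
            "agent_id",
            "exposure_pattern",
            "desert_history",
            "v_hat_final",
            "p_final",
            "mean_servings",
        ],
    )
    return trajectories, final


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Long-form table of recorded steps across agents (CSV interchange)."""
    if not trajectories:
        return pd.DataFrame(
            columns=[
                "agent_id",
                "step",
                "v_hat_H",
                "p_choice",
                "situation",
                "consumed_healthy",
                "servings",
            ]
        )
    return pd.concat([t.to_frame() for t in trajectories], ignore_index=True)


def trajectories_from_frame(df: pd.DataFrame) -> list[Trajectory]:
    """Rebuild per-agent trajectories from the long-form table.

    End-of-study summaries are recovered from the last recorded step;
    ``mean_servings`` is not stored per step and is returned as NaN.
    """
    out: list[Trajectory] = []
    for agent_id, g in df.groupby("agent_id", sort=True):
        g = g.sort_values("step")
        v = g["v_hat_H"].to_numpy(dtype=float)
        out.append(
            Trajectory(
                agent_id=int(agent_id),
                step=g["step"].to_numpy(dtype=np.int64),
                v_hat_H=v,
                p_choice=g["p_choice"].to_numpy(dtype=float),
                healthy_only=(g["situation"] == "healthy_only").to_numpy(),
                consumed_healthy=g["consumed_healthy"].to_numpy().astype(bool),
                servings=g["servings"].to_numpy(dtype=np.int64),
                final_v=float(v[-1]),
                final_p=float(v[-1] / (1.0 + v[-1])),
                mean_servings=float("nan"),
            )
        )
    return out
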