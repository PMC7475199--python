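"""Synthetic cohorts emulating the Arkansas elementary-school population.

Agents are followed from kindergarten through grade 6 (seven grade-years).
Each agent carries a 7-digit binary FFVP exposure pattern (digit order
K, 1, 2, 3, 4, 5, 6; 1 = attended an FFVP school that grade), a 7-digit
food-desert history on the same index, and a learning speed.

Generation is stratified on the four (ever-desert x ever-FFVP) cells: the
configured cell counts are realized exactly, so the cohort's marginal
fractions are a construction, not a sampling outcome.  Within cells,
exposure patterns are drawn from a configurable weight table (by default
concentrated on contiguous runs of grant years) and desert histories follow
a yearly two-state flip chain, conditioned on at least one desert year for
ever-desert agents.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PreferenceState

__all__ = [
    "GRADES",
    "N_GRADES",
    "ARKANSAS_CELL_COUNTS",
    "AlphaSpec",
    "CohortConfig",
    "AgentRecord",
    "decode_pattern",
    "enumerate_patterns",
    "default_pattern_weights",
    "assign_alpha",
    "generate_cohort",
    "cohort_to_csv",
    "cohort_from_csv",
]

GRADES: tuple[str, ...] = ("K", "1", "2", "3", "4", "5", "6")
N_GRADES = len(GRADES)

#: Joint (ever-desert x ever-FFVP) cell counts of the two Arkansas
#: kindergarten cohorts (2008/09 and 2009/10) the model tracks, keyed as
#: (ever_desert, ever_ffvp).  They sum to the 35,981 student-agents.
ARKANSAS_CELL_COUNTS: dict[tuple[bool, bool], int] = {
    (False, False): 7942,
    (False, True): 2591,
    (True, False): 17598,
    (True, True): 7850,
}


def _validate_bits(bits: str, what: str) -> str:
    if len(bits) != N_GRADES or any(c not in "01" for c in bits):
        raise ValueError(
            f"{what} must be a {N_GRADES}-character binary string, got {bits!r}"
        )
    return bits


def decode_pattern(pattern: str) -> tuple[str, ...]:
    """Grades (in K..6 order) during which the pattern shows FFVP exposure.

    >>> decode_pattern("1010000")
    ('K', '2')
    """
    _validate_bits(pattern, "exposure pattern")
    return tuple(g for g, c in zip(GRADES, pattern) if c == "1")


def enumerate_patterns() -> list[str]:
    """All 128 possible K-6 exposure patterns, in lexicographic order."""
    return ["".join(bits) for bits in itertools.product("01", repeat=N_GRADES)]


def default_pattern_weights(run_decay: float = 0.8) -> dict[str, float]:
    """Default exposure-pattern distribution for ever-exposed agents.

    Schools tend to hold or lose FFVP grants over consecutive years, so mass
    is placed on the 28 contiguous-run patterns (start grade s, run length
    L >= 1), with weight proportional to ``run_decay**(L-1)``: short runs are
    common and the full K-6 run is rare (~1.4% at the default decay, echoing
    how few students keep the program every year).  Normalized to sum to 1.
    """
    if not 0 < run_decay <= 1:
        raise ValueError("run_decay must be in (0, 1]")
    weights: dict[str, float] = {}
    for start in range(N_GRADES):
        for length in range(1, N_GRADES - start + 1):
            bits = ["0"] * N_GRADES
            bits[start : start + length] = "1" * length
            weights["".join(bits)] = run_decay ** (length - 1)
    total = sum(weights.values())
    return {p: w / total for p, w in weights.items()}


@dataclass(frozen=True)
class AlphaSpec:
    """Distribution of agent learning speeds.

    ``family`` is ``"constant"`` (all agents share ``value``) or
    ``"uniform"`` (independent draws on [lo, hi]).  Bounds must lie in
    (0, 1].  The default is the calibrated constant; heterogeneity across
    agents is available but the aggregate calibration never identifies a
    spread, so it is opt-in.
    """

    family: str = "constant"
    value: float = 0.005
    lo: float = 0.01
    hi: float = 0.10

    def __post_init__(self) -> None:
        if self.family not in ("constant", "uniform"):
            raise ValueError(f"unsupported alpha family {self.family!r}")
        if self.family == "constant":
            if not 0 < self.value <= 1:
                raise ValueError("constant alpha must be in (0, 1]")
        else:
            if not (0 < self.lo <= self.hi <= 1):
                raise ValueError(
                    f"uniform alpha bounds must satisfy 0 < lo <= hi <= 1, "
                    f"got lo={self.lo}, hi={self.hi}"
                )


def assign_alpha(spec: AlphaSpec, rng: np.random.Generator, size: int | None = None):
    """Draw learning speed(s) from the configured family; values in (0, 1]."""
    if spec.family == "constant":
        return spec.value if size is None else np.full(size, spec.value)
    if size is None:
        return float(rng.uniform(spec.lo, spec.hi))
    return rng.uniform(spec.lo, spec.hi, size=size)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the stratified cohort generator.

    ``cell_counts`` maps (ever_desert, ever_ffvp) to exact agent counts and
    must sum to ``n_agents``.  ``pattern_weights`` is the distribution over
    nonzero exposure patterns used in ever-FFVP cells.
    ``desert_flip_prob`` is the symmetric yearly probability that a census
    block changes desert status; ``initial_desert_prob`` is the chance an
    ever-desert agent starts kindergarten in a desert (desert status is
    persistent, so this is high).
    """

    n_agents: int = 35981
    cell_counts: dict[tuple[bool, bool], int] = field(
        default_factory=lambda: dict(ARKANSAS_CELL_COUNTS)
    )
    pattern_weights: dict[str, float] = field(default_factory=default_pattern_weights)
    desert_flip_prob: float = 0.05
    initial_desert_prob: float = 0.90
    alpha_spec: AlphaSpec = field(default_factory=AlphaSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_agents < 0:
            problems.append(f"n_agents must be >= 0, got {self.n_agents}")
        if set(self.cell_counts) != {(d, f) for d in (False, True) for f in (False, True)}:
            problems.append("cell_counts must have the four (ever_desert, ever_ffvp) keys")
        elif any(c < 0 for c in self.cell_counts.values()):
            problems.append("cell_counts must be nonnegative")
        elif sum(self.cell_counts.values()) != self.n_agents:
            problems.append(
                f"cell_counts sum to {sum(self.cell_counts.values())}, "
                f"expected n_agents={self.n_agents}"
            )
        if self.pattern_weights:
            for p in self.pattern_weights:
                _validate_bits(p, "pattern_weights key")
            if "0" * N_GRADES in self.pattern_weights:
                problems.append("pattern_weights must not include the all-zero pattern")
            total = sum(self.pattern_weights.values())
            if not np.isclose(total, 1.0):
                problems.append(f"pattern_weights sum to {total}, expected 1")
            if any(w < 0 for w in self.pattern_weights.values()):
                problems.append("pattern_weights must be nonnegative")
        else:
            problems.append("pattern_weights must be non-empty")
        if not 0 <= self.desert_flip_prob <= 1:
            problems.append("desert_flip_prob must be in [0, 1]")
        if not 0 <= self.initial_desert_prob <= 1:
            problems.append("initial_desert_prob must be in [0, 1]")
        if problems:
            raise ValueError("invalid cohort config: " + "; ".join(problems))


@dataclass(frozen=True)
class AgentRecord:
    """One simulated student: identifiers, exposures, and initial state.

    Exposure pattern and desert history must be binary strings of equal
    length — 7 digits (K-6) for the standard study schedule, but shorter
    horizons are allowed for single-year designs such as the calibration
    arms.
    """

    agent_id: int
    exposure: str
    desert: str
    alpha: float

    def __post_init__(self) -> None:
        for bits, what in ((self.exposure, "exposure pattern"), (self.desert, "desert history")):
            if not bits or any(c not in "01" for c in bits):
                raise ValueError(f"{what} must be a non-empty binary string, got {bits!r}")
        if len(self.exposure) != len(self.desert):
            raise ValueError("exposure pattern and desert history lengths must match")

    @property
    def state(self) -> PreferenceState:
        """Initial (unformed) preference state for this agent."""
        return PreferenceState(v_hat_H=0.0, alpha=self.alpha)

    @property
    def ever_ffvp(self) -> bool:
        return "1" in self.exposure

    @property
    def ever_desert(self) -> bool:
        return "1" in self.desert


def _desert_histories(
    n: int, ever: bool, flip_prob: float, init_prob: float, rng: np.random.Generator
) -> list[str]:
    """Yearly two-state flip chains; ever-desert rows are conditioned on >=1
    desert year by rejection resampling."""
    if not ever:
        return ["0" * N_GRADES] * n
    if n == 0:
        return []
    chains = np.zeros((n, N_GRADES), dtype=np.int8)
    todo = np.arange(n)
    while todo.size:
        m = todo.size
        state = (rng.random(m) < init_prob).astype(np.int8)
        chains[todo, 0] = state
        for year in range(1, N_GRADES):
            flip = rng.random(m) < flip_prob
            state = np.where(flip, 1 - state, state)
            chains[todo, year] = state
        todo = todo[chains[todo].sum(axis=1) == 0]
    return ["".join(map(str, row)) for row in chains]


def generate_cohort(cfg: CohortConfig) -> list[AgentRecord]:
    """Build the stratified cohort; deterministic for a fixed ``cfg.seed``.

    Realized (ever-desert x ever-FFVP) cell counts equal ``cfg.cell_counts``
    exactly.  Agents are numbered 0..n-1 in fixed cell order (non-desert
    before desert, unexposed before exposed).
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    patterns = sorted(cfg.pattern_weights)
    probs = np.array([cfg.pattern_weights[p] for p in patterns])
    probs = probs / probs.sum()

    records: list[AgentRecord] = []
    agent_id = 0
    for ever_desert in (False, True):
        for ever_ffvp in (False, True):
            n = cfg.cell_counts[(ever_desert, ever_ffvp)]
            if ever_ffvp:
                idx = rng.choice(len(patterns), size=n, p=probs)
                exposures = [patterns[i] for i in idx]
            else:
                exposures = ["0" * N_GRADES] * n
            deserts = _desert_histories(
                n, ever_desert, cfg.desert_flip_prob, cfg.initial_desert_prob, rng
            )
            alphas = assign_alpha(cfg.alpha_spec, rng, size=n)
            for exp, des, alpha in zip(exposures, deserts, alphas):
                records.append(AgentRecord(agent_id, exp, des, float(alpha)))
                agent_id += 1
    return records


def cohort_to_csv(cohort: list[AgentRecord], path: str | Path) -> None:
    """Write the cohort as UTF-8 CSV with a fixed column order."""
    df = pd.DataFrame(
        {
            "agent_id": [a.agent_id for a in cohort],
            "exposure_pattern": [a.exposure for a in cohort],
            "desert_history": [a.desert for a in cohort],
            "alpha": [a.alpha for a in cohort],
        }
    )
    df.to_csv(path, index=False, encoding="utf-8")


def cohort_from_csv(path: str | Path) -> list[AgentRecord]:
    """Read a cohort CSV (see :func:`cohort_to_csv` for the schema)."""
    df = pd.read_csv(
        path, dtype={"exposure_pattern": str, "desert_history": str}, encoding="utf-8"
    )
    required = {"agent_id", "exposure_pattern", "desert_history", "alpha"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return [
        AgentRecord(int(r.agent_id), r.exposure_pattern, r.desert_history, float(r.alpha))
        for r in df.itertuples(index=False)
    ]
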