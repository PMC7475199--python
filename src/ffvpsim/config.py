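"""YAML run configuration: schema, validation, and object construction.

A run config is a mapping with a master ``seed``, an ``output_dir``, an
optional ``log_level``, and per-stage blocks (``cohort``, ``simulation``,
``calibration``, ``reporting``).  Validation is strict — unknown keys are
rejected — and aggregated: all problems are reported in a single error
rather than one at a time.

Stage seeds are derived from the master seed through named substreams
(stage index folded into a :class:`numpy.random.SeedSequence`), so a stage
rerun in isolation reproduces its slice of a full pipeline run.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .calibrate import CalibrationTarget, ModelParams, SearchSpace
from .cohort import AlphaSpec, CohortConfig, default_pattern_weights
from .core import EnvironmentParams, ServingModel
from .simulate import SimulationConfig

__all__ = ["ConfigError", "RunConfig", "load_config", "stage_seed"]

_STAGES = {"cohort": 1, "simulation": 2, "calibration": 3, "reporting": 4}

_CELL_KEYS = {
    "never_desert_never_ffvp": (False, False),
    "never_desert_ffvp": (False, True),
    "desert_never_ffvp": (True, False),
    "desert_ffvp": (True, True),
}


class ConfigError(ValueError):
    """Aggregated configuration problem list."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


def stage_seed(master_seed: int, stage: str) -> int:
    """Named substream seed for a pipeline stage."""
    return int(
        np.random.SeedSequence([master_seed, _STAGES[stage]]).generate_state(1)[0]
    )


@dataclass
class RunConfig:
    """Validated configuration objects for each pipeline stage."""

    seed: int
    output_dir: Path
    log_level: str
    cohort: CohortConfig | None
    simulation: SimulationConfig | None
    calibration_target: CalibrationTarget | None
    calibration_space: SearchSpace | None
    base_params: ModelParams
    report_patterns: list[str]
    raw: dict = field(repr=False, default_factory=dict)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.raw, sort_keys=True).encode()
        ).hexdigest()


def _check_keys(block: dict, allowed: set[str], where: str, problems: list[str]) -> None:
    for key in block:
        if key not in allowed:
            problems.append(f"{where}: unknown key {key!r}")


def _build_cohort(block: dict, seed: int, problems: list[str]) -> CohortConfig | None:
    allowed = {
        "n_agents",
        "cell_counts",
        "pattern_weights",
        "run_decay",
        "desert_flip_prob",
        "initial_desert_prob",
        "alpha",
    }
    _check_keys(block, allowed, "cohort", problems)
    kwargs: dict = {"seed": seed}
    if "cell_counts" in block:
        cells = block["cell_counts"]
        if set(cells) != set(_CELL_KEYS):
            problems.append(
                f"cohort.cell_counts: expected keys {sorted(_CELL_KEYS)}, "
                f"got {sorted(cells)}"
            )
        else:
            kwargs["cell_counts"] = {_CELL_KEYS[k]: int(v) for k, v in cells.items()}
            kwargs.setdefault("n_agents", sum(kwargs["cell_counts"].values()))
    if "n_agents" in block:
        kwargs["n_agents"] = int(block["n_agents"])
        if "cell_counts" not in block:
            # split n_agents across cells in the default joint proportions
            from .cohort import ARKANSAS_CELL_COUNTS

            n = kwargs["n_agents"]
            total = sum(ARKANSAS_CELL_COUNTS.values())
            counts = {
                k: n * v // total for k, v in ARKANSAS_CELL_COUNTS.items()
            }
            counts[(True, True)] += n - sum(counts.values())
            kwargs["cell_counts"] = counts
    if "pattern_weights" in block:
        kwargs["pattern_weights"] = {
            str(k): float(v) for k, v in block["pattern_weights"].items()
        }
    elif "run_decay" in block:
        kwargs["pattern_weights"] = default_pattern_weights(float(block["run_decay"]))
    for key in ("desert_flip_prob", "initial_desert_prob"):
        if key in block:
            kwargs[key] = float(block[key])
    if "alpha" in block:
        spec = dict(block["alpha"])
        _check_keys(spec, {"family", "value", "lo", "hi"}, "cohort.alpha", problems)
        try:
            kwargs["alpha_spec"] = AlphaSpec(**spec)
        except (TypeError, ValueError) as e:
            problems.append(f"cohort.alpha: {e}")
    try:
        return CohortConfig(**kwargs)
    except (TypeError, ValueError) as e:
        problems.append(f"cohort: {e}")
        return None


def _build_env(block: dict, where: str, problems: list[str]) -> EnvironmentParams:
    _check_keys(block, {"p1", "p2", "a"}, where, problems)
    try:
        return EnvironmentParams(**{k: float(v) for k, v in block.items()})
    except (TypeError, ValueError) as e:
        problems.append(f"{where}: {e}")
        return EnvironmentParams()


def _build_simulation(
    block: dict, seed: int, problems: list[str]
) -> SimulationConfig | None:
    allowed = {
        "days_per_year",
        "n_years",
        "record_every",
        "gamma_per_day",
        "end_servings_mode",
        "env",
        "lam",
    }
    _check_keys(block, allowed, "simulation", problems)
    kwargs: dict = {"seed": seed}
    for key in ("days_per_year", "n_years", "record_every"):
        if key in block:
            kwargs[key] = int(block[key])
    if "gamma_per_day" in block:
        kwargs["gamma_per_day"] = bool(block["gamma_per_day"])
    if "end_servings_mode" in block:
        kwargs["end_servings_mode"] = str(block["end_servings_mode"])
    if "env" in block:
        kwargs["env"] = _build_env(dict(block["env"]), "simulation.env", problems)
    if "lam" in block:
        try:
            kwargs["serving_model"] = ServingModel(float(block["lam"]))
        except ValueError as e:
            problems.append(f"simulation.lam: {e}")
    try:
        return SimulationConfig(**kwargs)
    except (TypeError, ValueError) as e:
        problems.append(f"simulation: {e}")
        return None


def _build_calibration(
    block: dict, seed: int, problems: list[str]
) -> tuple[CalibrationTarget | None, SearchSpace | None]:
    _check_keys(block, {"target", "space"}, "calibration", problems)
    target = None
    space = SearchSpace()
    tblock = dict(block.get("target", {}))
    allowed = {"one_year_effect", "tolerance", "n_rep", "desert_frac", "days"}
    _check_keys(tblock, allowed, "calibration.target", problems)
    try:
        target = CalibrationTarget(
            seed=seed, **{k: v for k, v in tblock.items() if k in allowed}
        )
    except (TypeError, ValueError) as e:
        problems.append(f"calibration.target: {e}")
    sblock = dict(block.get("space", {}))
    allowed = {"a_range", "alpha_range", "lam_range", "n_grid", "n_refine", "shrink"}
    _check_keys(sblock, allowed, "calibration.space", problems)
    try:
        for key in ("a_range", "alpha_range", "lam_range"):
            if sblock.get(key) is not None:
                sblock[key] = tuple(float(x) for x in sblock[key])
        space = SearchSpace(**sblock)
    except (TypeError, ValueError) as e:
        problems.append(f"calibration.space: {e}")
    return target, space


def load_config(
    path: str | Path,
    seed_override: int | None = None,
    require: tuple[str, ...] = ("cohort", "simulation"),
) -> RunConfig:
    """Load and strictly validate a YAML run configuration.

    ``seed_override`` replaces the file's master seed (recorded in the
    provenance manifest by the CLI).  ``require`` lists the stage blocks
    that must be present for the intended command.  All schema problems are
    raised together as a single :class:`ConfigError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])

    problems: list[str] = []
    allowed_top = {"seed", "output_dir", "log_level", "cohort", "simulation", "calibration", "reporting"}
    _check_keys(raw, allowed_top, "top level", problems)
    for block in require:
        if block not in raw:
            problems.append(f"missing required block {block!r}")

    seed = int(raw.get("seed", 0)) if seed_override is None else int(seed_override)
    output_dir = Path(raw.get("output_dir", "ffvpsim_out"))
    log_level = str(raw.get("log_level", "INFO")).upper()
    if log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
        problems.append(f"log_level: unknown level {log_level!r}")

    cohort = None
    if isinstance(raw.get("cohort"), dict):
        cohort = _build_cohort(dict(raw["cohort"]), stage_seed(seed, "cohort"), problems)
    elif "cohort" in raw:
        problems.append("cohort: must be a mapping")

    simulation = None
    if isinstance(raw.get("simulation"), dict):
        simulation = _build_simulation(
            dict(raw["simulation"]), stage_seed(seed, "simulation"), problems
        )
    elif "simulation" in raw:
        problems.append("simulation: must be a mapping")
    elif "simulation" not in require:
        simulation = SimulationConfig(seed=stage_seed(seed, "simulation"))

    target, space = None, None
    if isinstance(raw.get("calibration"), dict):
        target, space = _build_calibration(
            dict(raw["calibration"]), stage_seed(seed, "calibration"), problems
        )
    elif "calibration" in raw:
        problems.append("calibration: must be a mapping")

    report_patterns: list[str] = []
    if isinstance(raw.get("reporting"), dict):
        _check_keys(dict(raw["reporting"]), {"patterns"}, "reporting", problems)
        report_patterns = [str(p) for p in raw["reporting"].get("patterns", [])]
    elif "reporting" in raw:
        problems.append("reporting: must be a mapping")

    if problems:
        raise ConfigError(problems)

    base = ModelParams(
        env=simulation.env if simulation else EnvironmentParams(),
        alpha=(
            cohort.alpha_spec.value
            if cohort and cohort.alpha_spec.family == "constant"
            else ModelParams().alpha
        ),
        serving_model=simulation.serving_model if simulation else ServingModel(),
    )
    return RunConfig(
        seed=seed,
        output_dir=output_dir,
        log_level=log_level,
        cohort=cohort,
        simulation=simulation,
        calibration_target=target,
        calibration_space=space,
        base_params=base,
        report_patterns=report_patterns,
        raw=raw,
    )
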