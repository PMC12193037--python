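"""Frozen fitted parameter sets and canned circuits for tests and demos.

Each fixture is a parameter set found once by this package's own genetic
algorithm (seeded runs at the 1 Hz rhythm target) and committed as JSON, so
tests and sweeps never need to re-run optimisation.  ``generate_fixtures``
materialises the corresponding circuit config files and a set of synthetic
analysis traces under a directory.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np

from . import io as wio
from . import problems
from .circuit import CircuitConfig, match, modify_connection
from .evolve import EAProblem
from .simulate import SimulationResult

FIXTURE_NAMES = (
    "two_node",
    "functional_unit",
    "coupled_body",
    "coupled_head",
    "simplified_worm",
)


def _fixture_dir():
    return resources.files("wormloop") / "fixtures"


def fixture_record(name: str) -> dict:
    """Raw fixture record: fitted params plus provenance and reference stats."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; have {FIXTURE_NAMES}")
    path = _fixture_dir() / f"{name}.json"
    return json.loads(path.read_text())


def fixture_params(name: str) -> dict[str, float]:
    return dict(fixture_record(name)["params"])


def fixture_problem(name: str) -> EAProblem:
    return problems.PROBLEM_FACTORIES[name]()


def fixture_config(name: str) -> CircuitConfig:
    problem = fixture_problem(name)
    return problem.builder(fixture_params(name))


def simulate_fixture(
    name: str,
    duration: float = 20.0,
    seed: int | None = 0,
    params_override: dict | None = None,
) -> SimulationResult:
    """Simulate a fixture from its committed fitted parameters."""
    problem = fixture_problem(name)
    params = fixture_params(name)
    if params_override:
        params.update(params_override)
    return problem.simulate(params, seed=seed, duration=duration)


def simulate_modified(
    name: str,
    modifications: list[tuple] = (),
    duration: float = 20.0,
    seed: int | None = 0,
) -> SimulationResult:
    """Fixture simulation after wiring surgery.

    ``modifications`` is a list of ``(selector, scale)`` pairs applied with
    :func:`wormloop.circuit.modify_connection` (scale 0 = ablation); all
    other fitted parameters stay untouched.
    """
    problem = fixture_problem(name)
    params = fixture_params(name)
    config = problem.builder(params)
    for selector, scale in modifications:
        config = modify_connection(config, selector, scale)
    from .geometry import EnvironmentParams
    from .simulate import run

    env = EnvironmentParams(params["C_N"], params["C_T"])
    return run(config, env=env, duration=duration, dt=problem.dt,
               stride=problem.stride, init_mode=problem.init_mode, seed=seed)


def simulate_scaled_feedback(
    name: str,
    nf_scale: float = 1.0,
    pf_scale: float = 1.0,
    duration: float = 20.0,
    seed: int | None = 0,
) -> SimulationResult:
    """Fixture simulation with the feedback weights scaled in the wiring.

    ``nf_scale``/``pf_scale`` multiply every negative / positive feedback
    connection relative to its fitted strength (0 = ablation).
    """
    config = fixture_config(name)
    mods = []
    if nf_scale != 1.0:
        mods.append((match(kind="feedback", polarity="negative"), nf_scale))
    if pf_scale != 1.0 and any(f.polarity == "positive" for f in config.feedbacks):
        mods.append((match(kind="feedback", polarity="positive"), pf_scale))
    return simulate_modified(name, mods, duration, seed)


def synthetic_traces(seed: int = 0, duration: float = 20.0,
                     dt: float = 1e-3) -> dict[str, np.ndarray]:
    """Deterministic synthetic traces for analysis-module tests."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, dt)
    return {
        "t": t,
        "sin_1hz": np.sin(2 * np.pi * 1.0 * t),
        "sin_0p7hz_noisy": np.sin(2 * np.pi * 0.7 * t)
        + 0.1 * rng.standard_normal(len(t)),
        "flat": np.zeros(len(t)),
        "offset_sine": 3.0 + 2.0 * np.sin(2 * np.pi * 1.0 * t),
    }


def generate_fixtures(seed: int = 0, outdir: str | Path = "fixtures_out") -> Path:
    """Write canned circuit configs, fitted parameters and synthetic traces.

    The output is bit-stable for a given seed: circuit YAML per fixture, the
    committed fitted parameter JSONs, and a CSV of synthetic traces.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in FIXTURE_NAMES:
        record = fixture_record(name)
        (outdir / f"{name}_params.json").write_text(
            json.dumps(record, indent=2, sort_keys=True)
        )
        wio.save_config(fixture_config(name), outdir / f"{name}.yaml")
    traces = synthetic_traces(seed)
    import pandas as pd

    pd.DataFrame(traces).to_csv(outdir / "synthetic_traces.csv", index=False)
    return outdir
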