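"""Coupled integration of the neural and mechanical state.

The membrane potentials x and the body coordinates (y, ydot) form one joint
state advanced by fixed-step classical Runge-Kutta (RK4); muscle deformation
is recomputed from the mechanical state inside every derivative evaluation,
so the neuro-mechanical coupling is simultaneous (no operator splitting).
Runs are deterministic given (config, geometry, environment, dt, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from .circuit import CircuitConfig
from .errors import IntegrationBlowUpError
from .geometry import BodyGeometry, BodyState, EnvironmentParams
from .kernel import CompiledModel, integrate, lower, measure, rhs
from .neural import NeuralState

DEFAULT_DT = 5e-4  # s
DEFAULT_STRIDE = 10
DEFAULT_BURN_IN = 0.2


@dataclass
class SimState:
    """Joint state at one instant."""

    t: float
    neural: NeuralState
    body: BodyState

    def pack(self) -> np.ndarray:
        return np.concatenate([self.neural.x, self.body.y, self.body.ydot])

    @classmethod
    def unpack(cls, t: float, vec: np.ndarray, n_nodes: int, dof: int) -> "SimState":
        return cls(
            t=t,
            neural=NeuralState(vec[:n_nodes].copy()),
            body=BodyState(vec[n_nodes:n_nodes + dof].copy(),
                           vec[n_nodes + dof:].copy()),
        )


@dataclass
class SimulationResult:
    """Recorded trajectory of one run plus reproduction metadata."""

    t: np.ndarray  # (n_rec,)
    x: np.ndarray  # (n_rec, N) membrane potentials, mV
    y: np.ndarray  # (n_rec, dof)
    ydot: np.ndarray  # (n_rec, dof)
    muscle_length: np.ndarray  # (n_rec, q) um
    deformation: np.ndarray  # (n_rec, q) um, delta = L - l
    centroid: np.ndarray  # (n_rec, 2) um
    head: np.ndarray  # (n_rec, 2) um
    node_ids: list[str]
    muscle_ids: list[str]
    metadata: dict = field(default_factory=dict)

    @property
    def dt_output(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0

    @property
    def duration(self) -> float:
        return float(self.t[-1])

    def potential(self, node_id: str) -> np.ndarray:
        return self.x[:, self.node_ids.index(node_id)]

    def delta(self, muscle_id: str) -> np.ndarray:
        return self.deformation[:, self.muscle_ids.index(muscle_id)]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format time series (column per recorded quantity)."""
        cols = {"t": self.t}
        for i, nid in enumerate(self.node_ids):
            cols[f"v_{nid}"] = self.x[:, i]
        for j, mid in enumerate(self.muscle_ids):
            cols[f"l_{mid}"] = self.muscle_length[:, j]
            cols[f"delta_{mid}"] = self.deformation[:, j]
        cols["centroid_x"] = self.centroid[:, 0]
        cols["centroid_y"] = self.centroid[:, 1]
        return pd.DataFrame(cols)

    def save_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path

    def save_summary(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.metadata, indent=2, sort_keys=True))
        return path

    def burn_slice(self, burn_in: float = DEFAULT_BURN_IN) -> slice:
        return slice(int(np.floor(burn_in * len(self.t))), None)


def _config_hash(config: CircuitConfig, geom: BodyGeometry,
                 env: EnvironmentParams, dt: float) -> str:
    blob = wio.dumps_config(config) + json.dumps(geom.to_dict()) + \
        f"{env.drag_normal}:{env.drag_tangent}:{dt}"
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def initial_conditions(
    config: CircuitConfig,
    geom: BodyGeometry,
    mode: str = "rest",
    seed: int | None = None,
    perturbation_mv: float = 1.0,
) -> SimState:
    """Rest: straight body, every potential at its leak equilibrium.

    ``perturbed`` adds small seeded Gaussian offsets (default 1 mV) to the
    potentials to break symmetry between dorsal and ventral populations.
    """
    neural = NeuralState.resting(config)
    body = BodyState.straight(geom)
    if mode == "perturbed":
        rng = np.random.default_rng(seed)
        neural.x = neural.x + perturbation_mv * rng.standard_normal(len(neural.x))
    elif mode != "rest":
        raise ValueError(f"unknown init mode {mode!r}")
    return SimState(0.0, neural, body)


def step(state: SimState, dt: float, model: CompiledModel) -> SimState:
    """One RK4 step of the joint state (library-level; runs use the
    compiled loop)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    s = state.pack()
    k1 = rhs(model, s)
    k2 = rhs(model, s + 0.5 * dt * k1)
    k3 = rhs(model, s + 0.5 * dt * k2)
    k4 = rhs(model, s + dt * k3)
    new = s + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    if not np.all(np.isfinite(new)):
        bad = _first_bad_label(new, model)
        raise IntegrationBlowUpError(bad, state.t + dt)
    return SimState.unpack(state.t + dt, new, model.n_nodes, model.dof)


def _first_bad_label(vec: np.ndarray, model: CompiledModel) -> str:
    idx = int(np.flatnonzero(~np.isfinite(vec))[0])
    if idx < model.n_nodes:
        return f"v[{model.config.node_ids[idx]}]"
    if idx < model.n_nodes + model.dof:
        return f"y[{idx - model.n_nodes}]"
    return f"ydot[{idx - model.n_nodes - model.dof}]"


def run(
    config: CircuitConfig,
    geom: BodyGeometry | None = None,
    env: EnvironmentParams | None = None,
    duration: float = 10.0,
    dt: float = DEFAULT_DT,
    stride: int = DEFAULT_STRIDE,
    init_mode: str = "rest",
    seed: int | None = None,
    model: CompiledModel | None = None,
) -> SimulationResult:
    """Simulate the coupled system and record the full trajectory.

    ``stride`` sets the output decimation (records every ``stride``-th step).
    Raises :class:`IntegrationBlowUpError` if the state leaves the finite
    range, naming the first offending variable.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if model is None:
        model = lower(config, geom, env)
    geom, env = model.geom, model.env
    state0 = initial_conditions(config, geom, init_mode, seed).pack()
    n_steps = int(round(duration / dt))
    times, states, ok, bad_step = integrate(model, state0, dt, n_steps, stride)
    if not ok:
        bad = _first_bad_label(states[-1], model)
        raise IntegrationBlowUpError(bad, bad_step * dt)

    lengths, centroid, head = measure(model, states)
    q = model.n_muscles
    muscle_length = lengths[:, model.muscle_slot] if q else np.empty((len(times), 0))
    deformation = model.muscle_rest[None, :] - muscle_length if q \
        else np.empty((len(times), 0))

    dof = model.dof
    n = model.n_nodes
    meta = {
        "circuit": config.name,
        "config_hash": _config_hash(config, geom, env, dt),
        "dt": dt,
        "stride": stride,
        "duration": duration,
        "init_mode": init_mode,
        "seed": seed,
        "integrator": "rk4-fixed",
        "n_neurons": model.n_neurons,
        "n_muscles": model.n_muscles,
        "n_segments": model.n_seg,
    }
    return SimulationResult(
        t=times,
        x=states[:, :n],
        y=states[:, n:n + dof],
        ydot=states[:, n + dof:],
        muscle_length=muscle_length,
        deformation=deformation,
        centroid=centroid,
        head=head,
        node_ids=list(config.node_ids),
        muscle_ids=list(config.muscle_ids),
        metadata=meta,
    )
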