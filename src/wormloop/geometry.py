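"""Rigid-body geometry of the 2-D articulated worm.

The body is a chain of T-shaped rigid rods joined by revolute joints.  In a
segment's body frame, +x points tailward: the anterior joint P sits at
(-h/2, 0), the posterior joint Q at (+h/2, 0), and the lateral muscle
attachment arms reach to +y (dorsal) and -y (ventral) at the anterior joint.
A muscle of unit ``u`` anchors at P of segment ``u`` and at P of segment
``u+1`` (= Q of segment ``u``), offset laterally on its side, so it runs
alongside segment ``u`` and couples adjacent rods.

Lengths are um, masses are model units (total body mass is a free scale;
drag, spring and muscle forces share it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit import N_SEGMENTS, REST_LENGTH_UM, WORM_LENGTH_UM

#: 90-degree rotation used throughout the planar kinematics
#: (I_tilde @ v rotates v counterclockwise by 90 degrees).
I_TILDE = np.array([[0.0, -1.0], [1.0, 0.0]])


@dataclass
class EnvironmentParams:
    """Low-Reynolds resistive drag coefficients (force per um/s, per segment).

    ``drag_normal`` acts on the velocity component normal to the segment
    axis, ``drag_tangent`` on the axial component; slender-body drag has
    normal > tangent, which is what makes undulation propulsive.
    """

    drag_normal: float = 1.0
    drag_tangent: float = 0.5

    def __post_init__(self) -> None:
        if self.drag_normal < 0 or self.drag_tangent < 0:
            raise ValueError("drag coefficients must be >= 0")


@dataclass
class BodyGeometry:
    masses: np.ndarray  # (n,)
    inertias: np.ndarray  # (n,)
    rho_p: np.ndarray  # (n, 2) body-frame anterior joint offsets
    rho_q: np.ndarray  # (n, 2) body-frame posterior joint offsets
    b_d: np.ndarray  # (n, 2) dorsal attachment offset from P (body frame)
    b_v: np.ndarray  # (n, 2) ventral attachment offset from P (body frame)
    rest_length: float = REST_LENGTH_UM

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        n = self.n_segments
        for name in ("inertias", "rho_p", "rho_q", "b_d", "b_v"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.masses <= 0) or np.any(self.inertias <= 0):
            raise ValueError("masses and inertias must be > 0")
        for name, shape in (("inertias", (n,)), ("rho_p", (n, 2)),
                            ("rho_q", (n, 2)), ("b_d", (n, 2)), ("b_v", (n, 2))):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} must have shape {shape}")

    @property
    def n_segments(self) -> int:
        return len(self.masses)

    @property
    def n_units(self) -> int:
        return self.n_segments - 1

    @property
    def dof(self) -> int:
        """Generalised coordinates: r1 (2) + one angle per segment."""
        return self.n_segments + 2

    @classmethod
    def default(
        cls,
        n_segments: int = N_SEGMENTS,
        worm_length: float = WORM_LENGTH_UM,
        total_mass: float = 1.0,
        half_width: float = 25.0,
        tapered: bool = False,
    ) -> "BodyGeometry":
        """Uniform-density chain of equal rods.

        With a constant ``half_width`` the straight pose leaves every muscle
        exactly at rest length.  ``tapered=True`` instead follows a smooth
        spindle profile approximating the worm's outline (the straight-pose
        lengths then deviate from rest length by well under 1 um).
        """
        h = worm_length / N_SEGMENTS
        m = np.full(n_segments, total_mass / n_segments)
        inertia = m * (h**2 + (2 * half_width) ** 2) / 12.0
        rho_p = np.tile([-h / 2.0, 0.0], (n_segments, 1))
        rho_q = np.tile([h / 2.0, 0.0], (n_segments, 1))
        # attachment arms live at the anterior joint of each segment
        xi = np.arange(n_segments) / max(n_segments, 1)
        if tapered:
            widths = half_width * np.sqrt(np.clip(4.0 * xi * (1.0 - xi), 0.0, 1.0))
            widths = np.maximum(widths, 2.0)
        else:
            widths = np.full(n_segments, half_width)
        b_d = np.column_stack([np.zeros(n_segments), widths])
        b_v = np.column_stack([np.zeros(n_segments), -widths])
        return cls(m, inertia, rho_p, rho_q, b_d, b_v, rest_length=h)

    def spring_table(self) -> list[tuple[int, str]]:
        """Every damped spring as (unit_index 1-based, side)."""
        return [(u, side) for u in range(1, self.n_units + 1)
                for side in ("dorsal", "ventral")]

    def to_dict(self) -> dict:
        return {
            "masses": self.masses.tolist(),
            "inertias": self.inertias.tolist(),
            "rho_p": self.rho_p.tolist(),
            "rho_q": self.rho_q.tolist(),
            "b_d": self.b_d.tolist(),
            "b_v": self.b_v.tolist(),
            "rest_length": self.rest_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BodyGeometry":
        return cls(**{k: np.asarray(v) if isinstance(v, list) else v
                      for k, v in d.items()})


@dataclass
class BodyState:
    """Generalised coordinates y = [r1 (2), theta_1..theta_n] and rates.

    ``theta_1`` is the absolute orientation of segment 1; subsequent angles
    are relative joint angles (counterclockwise positive), kept unwrapped.
    """

    y: np.ndarray
    ydot: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.ydot = np.asarray(self.ydot, dtype=float)
        if self.y.shape != self.ydot.shape or self.y.ndim != 1:
            raise ValueError("y and ydot must be matching 1-D vectors")

    @property
    def n_segments(self) -> int:
        return len(self.y) - 2

    @classmethod
    def straight(cls, geom: BodyGeometry, origin=(0.0, 0.0),
                 heading: float = 0.0) -> "BodyState":
        """Straight resting pose; segment 1's centroid at ``origin``.

        ``heading`` is the absolute orientation (rad) of the body axis; with
        the default 0 the worm lies along +x, head (segment 1) at the -x end.
        """
        y = np.zeros(geom.dof)
        y[0:2] = origin
        y[2] = heading
        return cls(y, np.zeros(geom.dof))
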