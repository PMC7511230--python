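"""Overdamped centrosome dynamics under cortical pulling forces.

Force balance for the two centrosomes couples viscous drag (eta) with a
central-spindle viscous element (nu) acting along the spindle axis
S_hat = (X1 - X2)/|X1 - X2|:

    eta X1' + nu ((X1' - X2') . S) S = F1
    eta X2' - nu ((X1' - X2') . S) S = F2

The linear system splits exactly into a translation mode (drag eta only)
and a separation mode whose along-axis component feels eta + 2 nu.
Positions are advanced by explicit Euler with the quasi-steady attachment
probabilities recomputed each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

from .geometry import (
    CellGeometry,
    LayoutSpec,
    _implicit_batch,
    distance_to_surface,
    place_cfgs,
)
from .model_core import CentrosomeState, ForceGenerator, MotorMTParams, net_forces

__all__ = [
    "MechanicsParams",
    "RampSchedule",
    "AblationEvent",
    "SimulationConfig",
    "Trajectory",
    "solve_velocities",
    "apply_ramp",
    "run_simulation",
    "remove_centrosome",
]

_RAMPABLE = (
    "nucleation_rate",
    "growth_speed",
    "catastrophe_rate",
    "detachment_rate",
    "capture_radius",
    "pull_force",
)


@dataclass(frozen=True)
class MechanicsParams:
    """Drag on each centrosome (eta) and central-spindle viscosity (nu),
    both in pN s/um."""

    centrosome_drag: float = 150.0
    spindle_viscosity: float = 100.0

    def __post_init__(self) -> None:
        if self.centrosome_drag <= 0:
            raise ValueError("centrosome_drag must be > 0")
        if self.spindle_viscosity < 0:
            raise ValueError("spindle_viscosity must be >= 0")


@dataclass(frozen=True)
class RampSchedule:
    """Linear ramp of one motor parameter over [t_start, t_end], clamped
    outside; models motor properties changing during anaphase."""

    parameter_name: str
    start_value: float
    end_value: float
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.parameter_name not in _RAMPABLE:
            raise ValueError(
                f"unknown ramp parameter {self.parameter_name!r}; one of {_RAMPABLE}"
            )
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")


@dataclass(frozen=True)
class AblationEvent:
    """Timed in-silico removal of one centrosome (index 0 or 1)."""

    time: float
    which: int


@dataclass
class SimulationConfig:
    geometry: CellGeometry = field(default_factory=CellGeometry)
    layout: LayoutSpec = field(default_factory=LayoutSpec)
    motor: MotorMTParams = field(default_factory=MotorMTParams)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    mode: Literal["stoichiometric", "nonstoichiometric"] = "stoichiometric"
    initial_positions: Optional[np.ndarray] = None  # (n, 3); default 11 um apart on x
    initial_separation: float = 11.0
    n_centrosomes: int = 2
    dt: float = 0.05
    t_max: float = 300.0
    speed_tolerance: float = 0.005
    converged_hold: float = 10.0
    ramp: Optional[RampSchedule] = None
    events: tuple[AblationEvent, ...] = ()
    record_stride: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_max <= 0:
            raise ValueError("dt and t_max must be positive")
        if self.n_centrosomes not in (1, 2):
            raise ValueError("n_centrosomes must be 1 or 2")
        if self.initial_positions is not None:
            self.initial_positions = np.atleast_2d(
                np.asarray(self.initial_positions, dtype=float)
            )
            self.n_centrosomes = len(self.initial_positions)

    def start_positions(self) -> np.ndarray:
        if self.initial_positions is not None:
            return self.initial_positions.copy()
        if self.n_centrosomes == 1:
            return np.zeros((1, 3))
        h = 0.5 * self.initial_separation
        return np.array([[-h, 0.0, 0.0], [h, 0.0, 0.0]])


@dataclass
class Trajectory:
    """Recorded centrosome motion.

    ``positions`` has shape (n_times, n_centrosomes, 3); inactive
    centrosomes repeat their last position.  ``length`` is pole-to-pole
    distance |X1 - X2| (nan once only one centrosome is active);
    ``center`` is the spindle midpoint.
    """

    times: np.ndarray
    positions: np.ndarray
    active: np.ndarray  # (n_times, n_centrosomes) bool
    termination: str = "t_max"
    config: Optional[SimulationConfig] = None

    @property
    def n_centrosomes(self) -> int:
        return self.positions.shape[1]

    @property
    def length(self) -> np.ndarray:
        if self.n_centrosomes < 2:
            return np.full(len(self.times), np.nan)
        L = np.linalg.norm(self.positions[:, 0] - self.positions[:, 1], axis=-1)
        both = self.active[:, 0] & self.active[:, 1]
        return np.where(both, L, np.nan)

    @property
    def center(self) -> np.ndarray:
        if self.n_centrosomes < 2:
            return self.positions[:, 0, :]
        return 0.5 * (self.positions[:, 0] + self.positions[:, 1])

    def final_positions(self) -> np.ndarray:
        return self.positions[-1]

    def final_length(self) -> float:
        return float(self.length[-1])


def solve_velocities(F1, F2, X1, X2, mech: MechanicsParams) -> tuple[np.ndarray, np.ndarray]:
    """Exact solution of the coupled force balance for two centrosomes.

    Sum mode: X1' + X2' = (F1 + F2)/eta.  Difference mode: transverse
    components relax with eta alone, the component along the spindle axis
    with eta + 2 nu.
    """
    F1 = np.asarray(F1, float)
    F2 = np.asarray(F2, float)
    X1 = np.asarray(X1, float)
    X2 = np.asarray(X2, float)
    sep = X1 - X2
    d = np.linalg.norm(sep)
    if d == 0:
        raise ValueError("coincident centrosomes: spindle axis undefined")
    S = sep / d
    eta = mech.centrosome_drag
    nu = mech.spindle_viscosity
    u = (F1 + F2) / eta
    dF = F1 - F2
    dF_par = np.dot(dF, S) * S
    dF_perp = dF - dF_par
    w = dF_perp / eta + dF_par / (eta + 2.0 * nu)
    return 0.5 * (u + w), 0.5 * (u - w)


def apply_ramp(params: MotorMTParams, t: float, schedule: Optional[RampSchedule]) -> MotorMTParams:
    """Motor parameters at time t under an optional linear ramp."""
    if schedule is None:
        return params
    if t <= schedule.t_start:
        v = schedule.start_value
    elif t >= schedule.t_end:
        v = schedule.end_value
    else:
        frac = (t - schedule.t_start) / (schedule.t_end - schedule.t_start)
        v = schedule.start_value + frac * (schedule.end_value - schedule.start_value)
    return params.replace(**{schedule.parameter_name: v})


def remove_centrosome(centrosomes: Sequence[CentrosomeState], which: int) -> None:
    """Flag a centrosome inactive (in-silico ablation); it no longer
    binds CFGs, competes, or moves, and the spindle coupling drops."""
    if not centrosomes[which].active:
        raise ValueError(f"centrosome {which} is already inactive")
    centrosomes[which].active = False


def run_simulation(config: SimulationConfig, cfgs: Optional[list[ForceGenerator]] = None) -> Trajectory:
    """Integrate centrosome motion until convergence, t_max, or cortex
    contact.

    Each step recomputes quasi-steady attachment probabilities jointly
    over active centrosomes, sums CFG forces, solves the force balance,
    and takes an explicit Euler step.  Convergence = every active
    centrosome slower than ``speed_tolerance`` for ``converged_hold``
    seconds.  A centrosome within one capture radius of the cortex (or
    outside it) terminates the run with ``cortex_contact`` — reached in
    practice only without stoichiometric interactions.
    """
    geom = config.geometry
    if cfgs is None:
        cfgs = place_cfgs(geom, config.layout)

    pos = config.start_positions()
    n = len(pos)
    for p in pos:
        if _implicit_batch(p[None, :], geom)[0] >= 0:
            raise ValueError("initial centrosome positions must be inside the cell")

    centros = [CentrosomeState(position=p.copy()) for p in pos]
    events = sorted(config.events, key=lambda e: e.time)
    ev_idx = 0

    dt = config.dt
    stride = max(1, int(config.record_stride))
    max_disp = 0.4  # um per step; steps are shortened adaptively beyond this

    times = [0.0]
    rec_pos = [np.array([c.position for c in centros])]
    rec_act = [np.array([c.active for c in centros])]
    termination = "t_max"
    slow_time = 0.0

    t = 0.0
    step = 0
    while t < config.t_max - 1e-12:
        while ev_idx < len(events) and events[ev_idx].time <= t:
            remove_centrosome(centros, events[ev_idx].which)
            ev_idx += 1
            slow_time = 0.0

        motor_t = apply_ramp(config.motor, t, config.ramp)
        forces, _ = net_forces(centros, cfgs, motor_t, mode=config.mode)

        active_idx = [i for i, c in enumerate(centros) if c.active]
        vel = np.zeros((n, 3))
        if len(active_idx) == 2:
            i, j = active_idx
            vel[i], vel[j] = solve_velocities(
                forces[i], forces[j], centros[i].position, centros[j].position,
                config.mechanics,
            )
        else:
            i = active_idx[0]
            vel[i] = forces[i] / config.mechanics.centrosome_drag

        speeds = np.linalg.norm(vel[active_idx], axis=-1)
        vmax = speeds.max()
        # adaptive step: never move more than max_disp in one step (the
        # runaway non-stoichiometric approach to the cortex)
        dt_step = min(dt, config.t_max - t,
                      max_disp / vmax if vmax > 0 else dt)
        if ev_idx < len(events):
            dt_step = min(dt_step, events[ev_idx].time - t)
        if dt_step <= 0:
            dt_step = min(dt, config.t_max - t)

        for i in active_idx:
            centros[i].position = centros[i].position + vel[i] * dt_step
        t += dt_step
        step += 1

        contact = False
        for i in active_idx:
            p = centros[i].position
            if (
                _implicit_batch(p[None, :], geom)[0] >= 0
                or distance_to_surface(p, geom) < motor_t.capture_radius
            ):
                contact = True
        if vmax < config.speed_tolerance:
            slow_time += dt_step
        else:
            slow_time = 0.0

        converged = (slow_time >= config.converged_hold
                     and ev_idx >= len(events))
        done = contact or converged or t >= config.t_max - 1e-12
        if step % stride == 0 or done:
            times.append(t)
            rec_pos.append(np.array([c.position for c in centros]))
            rec_act.append(np.array([c.active for c in centros]))

        if contact:
            termination = "cortex_contact"
            break
        if converged:
            termination = "converged"
            break

    return Trajectory(
        times=np.array(times),
        positions=np.array(rec_pos),
        active=np.array(rec_act),
        termination=termination,
        config=config,
    )
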