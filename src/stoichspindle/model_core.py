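"""Closed-form kinetics of the stoichiometric cortical-pulling model.

Astral microtubules (MTs) nucleate isotropically from a centrosome at rate
``gamma``, grow at speed ``Vg``, and undergo catastrophe at rate ``lam``.
A cortical force generator (CFG) is a disk of capture radius ``r`` on the
cell surface; a growing MT that enters the capture cone binds the CFG and
is pulled on with force ``f0`` along the MT, until it detaches at rate
``kappa``.  The stoichiometric rule — one MT per CFG at a time — makes
centrosomes compete for shared CFGs and is what stabilizes positioning.

Units package-wide: micrometres, seconds, piconewtons.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "MotorMTParams",
    "ForceGenerator",
    "CentrosomeState",
    "AttachmentSolution",
    "mt_steady_state_stats",
    "cone_fraction",
    "impingement_rate",
    "attachment_probabilities",
    "attachment_probability_ode_rhs",
    "cfg_force",
    "net_forces",
    "kappa_for_radius",
]


@dataclass(frozen=True)
class MotorMTParams:
    """Kinetic and mechanical constants of the MT-CFG system.

    Attributes
    ----------
    nucleation_rate : float
        MT nucleation rate gamma at the centrosome (1/s).
    growth_speed : float
        MT polymerization speed Vg (um/s).
    catastrophe_rate : float
        MT catastrophe rate lambda (1/s).
    detachment_rate : float
        MT-CFG detachment rate kappa (1/s).
    capture_radius : float
        Effective CFG capture-disk radius r (um); lumps the physical motor
        size with the distance an MT tip travels along the cortex.
    pull_force : float
        Force f0 exerted on a bound MT (pN).
    """

    nucleation_rate: float = 250.0
    growth_speed: float = 0.5
    catastrophe_rate: float = 0.025
    detachment_rate: float = 0.1
    capture_radius: float = 1.5
    pull_force: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "nucleation_rate",
            "growth_speed",
            "catastrophe_rate",
            "detachment_rate",
            "capture_radius",
            "pull_force",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")

    def replace(self, **kw) -> "MotorMTParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ForceGenerator:
    """A cortically anchored force generator (disk) on the cell surface."""

    id: int
    position: np.ndarray
    outward_normal: np.ndarray
    side: Literal["anterior", "posterior"]

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        n = np.asarray(self.outward_normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("outward_normal must be a unit vector")
        object.__setattr__(self, "outward_normal", n)


@dataclass
class CentrosomeState:
    """Centrosome position; ``active=False`` marks an ablated centrosome."""

    position: np.ndarray
    active: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class AttachmentSolution:
    """Quasi-steady attachment probabilities for centrosomes x CFGs.

    Arrays are shaped ``(n_centrosomes, n_cfgs)``.  ``probability[i, j]``
    is the stationary probability that CFG ``j`` holds an MT from
    centrosome ``i``; rows of inactive centrosomes are zero.  Per CFG the
    probabilities sum to < 1, the remainder being the unoccupied state.
    """

    probability: np.ndarray
    distance: np.ndarray
    direction: np.ndarray  # (n_centrosomes, n_cfgs, 3), unit vectors centrosome -> CFG
    omega: np.ndarray = field(default=None)  # impingement rates, same shape as probability


def mt_steady_state_stats(params: MotorMTParams) -> dict:
    """Steady-state statistics of the astral MT length distribution.

    The length density psi(l) = (gamma/Vg) exp(-l*lambda/Vg) gives

    - ``mt_count`` = gamma/lambda, total MTs (dimensionless count)
    - ``mean_length`` = Vg/lambda (um)
    - ``density_at_zero`` = gamma/Vg (MTs per um)
    """
    g, v, lam = params.nucleation_rate, params.growth_speed, params.catastrophe_rate
    return {
        "mt_count": g / lam,
        "mean_length": v / lam,
        "density_at_zero": g / v,
    }


def cone_fraction(d, cos_incidence, r):
    """Fraction chi of isotropically nucleated MTs whose direction lies in
    the capture cone of a CFG disk of radius ``r`` at distance ``d``.

    chi(d) = (xi.n)/2 * (1 - 1/sqrt(1 + (r/d)^2)),

    where ``cos_incidence`` = xi.n is the cosine between the
    centrosome-to-CFG direction and the disk's outward normal, clamped to
    [0, 1] (a disk seen edge-on or from behind captures nothing).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance d must be strictly positive")
    r = float(r)
    if r <= 0:
        raise ValueError("capture radius must be strictly positive")
    c = np.clip(np.asarray(cos_incidence, dtype=float), 0.0, 1.0)
    chi = 0.5 * c * (1.0 - 1.0 / np.sqrt(1.0 + (r / d) ** 2))
    return chi


def impingement_rate(d, cos_incidence, params: MotorMTParams, form: str = "exact"):
    """Rate Omega(d) at which growing MTs first impinge on a CFG.

    ``form='exact'``:  Omega = gamma * chi(d) * exp(-d*lambda/Vg), the
    steady-state flux of MT tips through the cone at distance d; bounded
    by gamma/2.

    ``form='approx'``: the small-angle form Omega ~ (gamma/4) *
    cos_incidence * (r/d)^2 * exp(-lambda*d/Vg), valid for r << d.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("centrosome and CFG positions must not coincide (d > 0)")
    g = params.nucleation_rate
    lam = params.catastrophe_rate
    v = params.growth_speed
    r = params.capture_radius
    survival = np.exp(-d * lam / v)
    if form == "exact":
        return g * cone_fraction(d, cos_incidence, r) * survival
    elif form == "approx":
        c = np.clip(np.asarray(cos_incidence, dtype=float), 0.0, 1.0)
        return 0.25 * g * c * (r / d) ** 2 * survival
    raise ValueError(f"unknown form {form!r}; use 'exact' or 'approx'")


def attachment_probabilities(omegas, kappa: float) -> np.ndarray:
    """Quasi-steady attachment probabilities at one CFG.

    For n centrosomes with impingement rates Omega_i at the CFG,

        P_i = Omega_i / (sum_j Omega_j + kappa),

    the stationary occupancies of the (n+1)-state one-site exclusion
    process (empty / bound-to-i).  n = 1 recovers Omega/(Omega + kappa);
    adding centrosomes can only reduce each P_i (competition).
    """
    if kappa <= 0:
        raise ValueError("detachment rate kappa must be strictly positive")
    om = np.asarray(omegas, dtype=float)
    if np.any(om < 0):
        raise ValueError("impingement rates must be non-negative")
    return om / (om.sum(axis=0) + kappa)


def attachment_probability_ode_rhs(P, omegas, kappa: float) -> np.ndarray:
    """Right-hand side of the explicit attachment dynamics
    dP_i/dt = Omega_i (1 - sum_j P_j) - kappa P_i, for validating the
    quasi-steady solution."""
    P = np.asarray(P, dtype=float)
    om = np.asarray(omegas, dtype=float)
    return om * (1.0 - P.sum(axis=0)) - kappa * P


def cfg_force(probability, direction, params: MotorMTParams,
              mode: str = "stoichiometric", omega=None) -> np.ndarray:
    """Mean force a CFG exerts on a centrosome.

    Stoichiometric: F = f0 * P * xi_hat, magnitude bounded by f0.
    Non-stoichiometric: every impinging MT is pulled, so the mean number
    of bound MTs is Omega/kappa and F = f0 * (Omega/kappa) * xi_hat,
    unbounded as d -> 0 (the destabilizing feedback).
    """
    direction = np.asarray(direction, dtype=float)
    if mode == "stoichiometric":
        w = np.asarray(probability, dtype=float)
    elif mode == "nonstoichiometric":
        if omega is None:
            raise ValueError("nonstoichiometric mode requires omega")
        w = np.asarray(omega, dtype=float) / params.detachment_rate
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return params.pull_force * w[..., None] * direction


def net_forces(
    centrosomes: Sequence[CentrosomeState],
    cfgs: Sequence[ForceGenerator],
    params: MotorMTParams,
    mode: str = "stoichiometric",
) -> tuple[np.ndarray, AttachmentSolution]:
    """Total pulling force on each centrosome from all CFGs.

    Per CFG, attachment probabilities are solved jointly over all *active*
    centrosomes (inactive ones neither bind nor compete); the force on
    centrosome i is the superposition F_i = sum_j f0 P_ij xi_hat_ij.

    Returns ``(forces, attachment)`` with ``forces`` shaped
    ``(n_centrosomes, 3)``; rows for inactive centrosomes are zero.
    """
    if len(cfgs) == 0:
        raise ValueError("at least one force generator is required")
    active = [i for i, c in enumerate(centrosomes) if c.active]
    if not active:
        raise ValueError("at least one active centrosome is required")

    pos = np.array([centrosomes[i].position for i in active])  # (na, 3)
    cfg_pos = np.array([f.position for f in cfgs])  # (m, 3)
    cfg_nrm = np.array([f.outward_normal for f in cfgs])  # (m, 3)

    sep = cfg_pos[None, :, :] - pos[:, None, :]  # (na, m, 3)
    dist = np.linalg.norm(sep, axis=-1)  # (na, m)
    if np.any(dist <= 0):
        raise ValueError("centrosome coincides with a force generator")
    xi = sep / dist[..., None]
    cosinc = np.einsum("imk,mk->im", xi, cfg_nrm)

    omega = impingement_rate(dist, cosinc, params)  # (na, m)
    prob = attachment_probabilities(omega, params.detachment_rate)
    per_cfg = cfg_force(prob, xi, params, mode=mode, omega=omega)  # (na, m, 3)
    f_active = per_cfg.sum(axis=1)  # (na, 3)

    n = len(centrosomes)
    forces = np.zeros((n, 3))
    P = np.zeros((n, len(cfgs)))
    D = np.full((n, len(cfgs)), np.nan)
    X = np.zeros((n, len(cfgs), 3))
    Om = np.zeros((n, len(cfgs)))
    for k, i in enumerate(active):
        forces[i] = f_active[k]
        P[i] = prob[k]
        D[i] = dist[k]
        X[i] = xi[k]
        Om[i] = omega[k]
    return forces, AttachmentSolution(probability=P, distance=D, direction=X, omega=Om)


def kappa_for_radius(r_new: float, r_old: float = 1.5, kappa: float = 0.1) -> float:
    """Detachment rate preserving the single-CFG quasi-steady attachment
    probability when the capture radius changes.

    In the small-angle regime Omega is proportional to r^2, so P =
    Omega/(Omega + kappa) is invariant under kappa' = kappa (r'/r)^2.
    Used to pack many small CFGs while conserving elongation dynamics.
    """
    if r_new <= 0 or r_old <= 0 or kappa <= 0:
        raise ValueError("radii and kappa must be strictly positive")
    return kappa * (r_new / r_old) ** 2
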