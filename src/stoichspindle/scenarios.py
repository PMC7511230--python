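"""Canonical experiment runners: reproducible ensembles of the headline
simulations (wild-type asymmetric spindle, symmetric layouts, single
asters, in-silico ablation, non-stoichiometric control, the two-plane
force toy) plus the cell-size and CFG-number sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dynamics import (
    AblationEvent,
    MechanicsParams,
    SimulationConfig,
    Trajectory,
    run_simulation,
)
from .geometry import CellGeometry, LayoutSpec, half_surface_area, place_cfgs
from .model_core import (
    CentrosomeState,
    ForceGenerator,
    MotorMTParams,
    kappa_for_radius,
    net_forces,
)
from .trait_analysis import TraitRecord, extract_traits, regress, traits_to_table

__all__ = [
    "ScenarioResult",
    "SCENARIO_NAMES",
    "run_scenario",
    "cell_size_sweep",
    "cfg_number_sweep",
    "two_plane_force_profile",
]

SCENARIO_NAMES = (
    "wildtype_asymmetric",
    "symmetric_par6",
    "single_centrosome",
    "ablation",
    "nonstoichiometric",
    "two_plane_toy",
    "initial_condition_ensemble",
)


@dataclass
class ScenarioResult:
    name: str
    trajectories: list[Trajectory]
    traits: Optional[pd.DataFrame] = None
    # ensemble mean/SD of L(t) and centre x(t) on a common grid
    grid_times: Optional[np.ndarray] = None
    length_mean: Optional[np.ndarray] = None
    length_sd: Optional[np.ndarray] = None
    center_mean: Optional[np.ndarray] = None
    center_sd: Optional[np.ndarray] = None
    extra: dict = field(default_factory=dict)

    def final_lengths(self) -> np.ndarray:
        return np.array([t.final_length() for t in self.trajectories])


def _ensemble_curves(trajs: list[Trajectory], n_grid: int = 200):
    t_end = min(tr.times[-1] for tr in trajs)
    grid = np.linspace(0.0, t_end, n_grid)
    Ls = np.array([np.interp(grid, tr.times, tr.length) for tr in trajs])
    Cs = np.array([np.interp(grid, tr.times, tr.center[:, 0]) for tr in trajs])
    return grid, Ls.mean(0), Ls.std(0), Cs.mean(0), Cs.std(0)


def _collect(name, trajs, geom) -> ScenarioResult:
    records = []
    for tr in trajs:
        if tr.n_centrosomes == 2 and tr.active[-1].all():
            records.append(extract_traits(tr, geom))
    res = ScenarioResult(name=name, trajectories=trajs)
    if records:
        res.traits = traits_to_table(records)
    if len(trajs) > 1 and all(tr.n_centrosomes == 2 for tr in trajs) and all(
        tr.active[-1].all() for tr in trajs
    ):
        (res.grid_times, res.length_mean, res.length_sd,
         res.center_mean, res.center_sd) = _ensemble_curves(trajs)
    return res


def run_scenario(
    name: str,
    overrides: Optional[dict] = None,
    n_configs: int = 8,
    seed: int = 0,
) -> ScenarioResult:
    """Run a named ensemble scenario.

    ``overrides`` are applied to the base :class:`SimulationConfig`
    fields.  ``n_configs`` independent CFG layouts (seeds derived from
    ``seed``) make up the ensemble.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; options: {SCENARIO_NAMES}")
    overrides = dict(overrides or {})
    geom = overrides.pop("geometry", CellGeometry())
    motor = overrides.pop("motor", MotorMTParams())
    mech = overrides.pop("mechanics", MechanicsParams())
    layout_kw = overrides.pop("layout", {})
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=max(n_configs, 1))

    def base_config(layout_seed, **kw) -> SimulationConfig:
        lay = LayoutSpec(seed=int(layout_seed), **layout_kw) if isinstance(
            layout_kw, dict) else layout_kw
        merged = {**overrides, **kw}
        return SimulationConfig(geometry=geom, layout=lay, motor=motor,
                                mechanics=mech, **merged)

    if name == "two_plane_toy":
        return _two_plane_scenario(motor, overrides)

    trajs: list[Trajectory] = []
    if name == "wildtype_asymmetric":
        for s in sub_seeds:
            trajs.append(run_simulation(base_config(s)))
    elif name == "symmetric_par6":
        layout_kw = {**(layout_kw if isinstance(layout_kw, dict) else {}),
                     "posterior_fraction": 0.5}
        for s in sub_seeds:
            lay = LayoutSpec(seed=int(s), **layout_kw)
            trajs.append(run_simulation(SimulationConfig(
                geometry=geom, layout=lay, motor=motor, mechanics=mech,
                **overrides)))
    elif name == "single_centrosome":
        # a lone aster in the uniformly covered cell centres itself
        layout_kw = {"posterior_fraction": 0.5,
                     **(layout_kw if isinstance(layout_kw, dict) else {})}
        for s in sub_seeds:
            lay = LayoutSpec(seed=int(s), **layout_kw)
            trajs.append(run_simulation(SimulationConfig(
                geometry=geom, layout=lay, motor=motor, mechanics=mech,
                n_centrosomes=1,
                initial_positions=np.array([[rng.uniform(-5, 5), 0.0, 0.0]]),
                **overrides)))
    elif name == "ablation":
        # in-silico centrosome removal in the uniform-coverage cell
        layout_kw = {"posterior_fraction": 0.5,
                     **(layout_kw if isinstance(layout_kw, dict) else {})}
        t_cut = overrides.pop("ablation_time", 250.0)
        t_max = overrides.pop("t_max", 600.0)
        for s in sub_seeds:
            lay = LayoutSpec(seed=int(s), **layout_kw)
            trajs.append(run_simulation(SimulationConfig(
                geometry=geom, layout=lay, motor=motor, mechanics=mech,
                events=(AblationEvent(time=t_cut, which=0),),
                t_max=t_max, **overrides)))
    elif name == "nonstoichiometric":
        for s in sub_seeds:
            trajs.append(run_simulation(base_config(s, mode="nonstoichiometric")))
    elif name == "initial_condition_ensemble":
        layout_seed = int(sub_seeds[0])
        cfgs = place_cfgs(geom, LayoutSpec(seed=layout_seed, **(
            layout_kw if isinstance(layout_kw, dict) else {})))
        for s in sub_seeds:
            r = np.random.default_rng(int(s))
            center = r.uniform(-2.0, 2.0, size=3) * np.array([1.0, 0.5, 0.5])
            half = 0.5 * 11.0
            init = np.array([center - [half, 0, 0], center + [half, 0, 0]])
            trajs.append(run_simulation(
                base_config(layout_seed, initial_positions=init), cfgs=cfgs))
        res = _collect(name, trajs, geom)
        res.extra["layout_seed"] = layout_seed
        return res
    return _collect(name, trajs, geom)


def two_plane_force_profile(
    motor: Optional[MotorMTParams] = None,
    plane_separation: float = 30.0,
    grid_half_spacing: float = 15.0,
    offsets: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Axial net force on a single centrosome between two parallel planes
    of CFGs (2 x 2 square grid per plane, normals facing the midplane).

    Restoring geometry: the nearer plane binds MTs with higher
    probability but pulls more obliquely, so its axial projection loses —
    the net force pushes the centrosome back to the midplane.
    """
    motor = motor or MotorMTParams()
    h = plane_separation / 2.0
    g = grid_half_spacing
    cfgs = []
    idx = 0
    for zsign in (+1.0, -1.0):
        for gx in (-g, g):
            for gy in (-g, g):
                cfgs.append(ForceGenerator(
                    id=idx, position=np.array([gx, gy, zsign * h]),
                    outward_normal=np.array([0.0, 0.0, zsign]), side="posterior"))
                idx += 1
    if offsets is None:
        offsets = np.linspace(-0.9 * h, 0.9 * h, 37)
    rows = []
    for dz in offsets:
        c = [CentrosomeState(np.array([0.0, 0.0, dz]))]
        F, _ = net_forces(c, cfgs, motor)
        rows.append({"offset": dz, "axial_force": F[0, 2]})
    return pd.DataFrame(rows)


def _two_plane_scenario(motor, overrides) -> ScenarioResult:
    profile = two_plane_force_profile(
        motor,
        plane_separation=overrides.pop("plane_separation", 30.0),
        grid_half_spacing=overrides.pop("grid_half_spacing", 15.0),
    )
    return ScenarioResult(name="two_plane_toy", trajectories=[],
                          extra={"force_profile": profile})


def cell_size_sweep(
    lengths=(44.0, 46.0, 48.0, 50.0, 52.0, 54.0),
    n_configs: int = 8,
    seed: int = 0,
    baseline_counts=(60, 40),
    overrides: Optional[dict] = None,
) -> dict:
    """Simulate cells of different lengths at fixed per-half CFG surface
    density and asymmetry; regress final spindle length on cell length.

    The CFG density of each half is pinned at the 50-um baseline
    (``baseline_counts`` CFGs on the posterior/anterior halves of the
    default cell); counts for other sizes follow from the half areas.
    Returns the trait table (one row per run) and the scaling fit.
    """
    lengths = np.asarray(lengths, dtype=float)
    if np.any((lengths < 30) | (lengths > 80)):
        raise ValueError("cell lengths outside the sane 30-80 um range")
    if np.ptp(lengths) == 0:
        raise ValueError("cell lengths are all equal; scaling regression undefined")
    overrides = dict(overrides or {})
    motor = overrides.pop("motor", MotorMTParams())
    mech = overrides.pop("mechanics", MechanicsParams())

    geom0 = CellGeometry()
    A0 = half_surface_area(geom0)
    dens_post = baseline_counts[0] / A0
    dens_ant = baseline_counts[1] / A0

    rng = np.random.default_rng(seed)
    records = []
    for L in lengths:
        geom = CellGeometry(Rx=L / 2.0)
        A = half_surface_area(geom)
        n_post = int(round(dens_post * A))
        n_ant = int(round(dens_ant * A))
        lay_kw = dict(n_total=n_post + n_ant,
                      posterior_fraction=n_post / (n_post + n_ant))
        for _ in range(n_configs):
            s = int(rng.integers(0, 2**31 - 1))
            cfg = SimulationConfig(
                geometry=geom, layout=LayoutSpec(seed=s, **lay_kw),
                motor=motor, mechanics=mech, **overrides)
            tr = run_simulation(cfg)
            rec = extract_traits(tr, geom)
            rec.line = f"CL{L:.0f}"
            records.append(rec)
    table = traits_to_table(records)
    fit = regress(table, "FL", "CL")
    return {"table": table, "scaling_fit": fit}


def cfg_number_sweep(
    n_values=(100, 400, 1600),
    co_scaling: str = "force",
    seed: int = 0,
    n_configs: int = 2,
    overrides: Optional[dict] = None,
) -> dict:
    """Vary the number of CFGs, optionally co-scaling other parameters.

    - ``co_scaling='force'``: hold N x f0 at the baseline 100 x 10 pN,
      which conserves the elongation dynamics.
    - ``co_scaling='radius_kappa'``: shrink the capture radius so the
      CFGs pack (r such that N disks fit) and rescale kappa with r^2 so
      the single-CFG attachment probability is unchanged.
    - ``co_scaling='none'``: change N alone (faster elongation, still
      stable).

    Returns per-N ensembles; all stoichiometric runs must remain stably
    positioned (no cortex contact).
    """
    if co_scaling not in ("force", "radius_kappa", "none"):
        raise ValueError("co_scaling must be force|radius_kappa|none")
    overrides = dict(overrides or {})
    base_motor = overrides.pop("motor", MotorMTParams())
    geom = overrides.pop("geometry", CellGeometry())
    rng = np.random.default_rng(seed)
    area = 2 * half_surface_area(geom)

    out = {}
    for N in n_values:
        motor = base_motor
        if co_scaling == "force":
            motor = motor.replace(pull_force=base_motor.pull_force * 100.0 / N)
        elif co_scaling == "radius_kappa":
            # keep disks to <15% surface coverage, then hold P invariant
            r_new = min(base_motor.capture_radius,
                        np.sqrt(0.15 * area / (np.pi * N)))
            motor = motor.replace(
                capture_radius=r_new,
                detachment_rate=kappa_for_radius(
                    r_new, base_motor.capture_radius, base_motor.detachment_rate),
            )
        if N * np.pi * motor.capture_radius**2 > 0.5 * area:
            raise ValueError(
                f"{N} CFGs of radius {motor.capture_radius} um cannot pack on "
                f"{area:.0f} um^2 of surface")
        trajs = []
        for _ in range(n_configs):
            s = int(rng.integers(0, 2**31 - 1))
            relax = 25 if N <= 400 else 5
            cfg = SimulationConfig(
                geometry=geom,
                layout=LayoutSpec(n_total=N, posterior_fraction=0.6, seed=s,
                                  relax_iters=relax),
                motor=motor, **overrides)
            trajs.append(run_simulation(cfg))
        out[N] = _collect(f"cfg_number_{N}", trajs, geom)
        out[N].extra["motor"] = motor
    return out
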