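"""Desk-scale adiabatic-bias Langevin dynamics on a toy bead chain.

The collective variable (CV) is the distance between the heavy-atom centre
of the N-terminal arrest-peptide residue and a fixed virtual point beyond
the tunnel mouth.  The ratchet-and-pawl bias is a one-sided harmonic whose
reference follows the best (smallest) CV value reached so far: it is
identically zero whenever the system moves toward the target and damps
fluctuations in the opposite direction only.

Engine unit system: kJ/mol, nm, amu, ps internally; the package-facing time
unit is ns.  The spring constant K is in (kJ/mol)/nm² with the conventional
½·K·Δρ² energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    AnalysisConfig,
    Entity,
    EventTable,
    Topology,
    Trajectory,
)
from .units import KB, PS_PER_NS, ang_to_nm, nm_to_ang


# ---------------------------------------------------------------------------
# Collective variable
# ---------------------------------------------------------------------------

def cv_value(frame: np.ndarray, topology: Topology,
             virtual_point: np.ndarray, residue: Optional[int] = None) -> float:
    """CV in nm: distance from the N-terminal AP residue's heavy-atom centre
    (equal atomic masses assumed for the bead models) to ``virtual_point``.

    ``frame`` and ``virtual_point`` are in Å (package convention).
    """
    if residue is None:
        residues = topology.ap_residues
        if not residues:
            raise ValueError("topology has no AP residues")
        residue = min(residues)
    idx = topology.ap_residue_atoms(residue, heavy_only=True)
    com = frame[idx].mean(axis=0)
    return float(ang_to_nm(np.linalg.norm(com - np.asarray(virtual_point))))


# ---------------------------------------------------------------------------
# Ratchet-and-pawl bias
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ABMDState:
    rho: float
    rho_best: float


@dataclass
class ABMDParams:
    K: float = 25.0              # (kJ/mol)/nm²
    cv_target: float = 0.0       # nm; arrival when rho <= cv_target + arrival_tol
    arrival_tol: float = 0.1     # nm
    time_bound: float = 100.0    # ns
    virtual_point: Optional[np.ndarray] = None  # Å

    def validate(self) -> None:
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if self.time_bound <= 0:
            raise ValueError("time_bound must be positive")


def abmd_update(state: ABMDState, rho_new: float, K: float
                ) -> Tuple[float, float, ABMDState]:
    """One ratchet update.

    Returns ``(energy kJ/mol, force (kJ/mol)/nm, new_state)`` where the force
    is the generalised force on the CV (negative = toward the target).  When
    the CV moves toward the target the bias is exactly zero and the pawl
    advances; otherwise the harmonic ½·K·(ρ−ρ_best)² acts.
    """
    if K < 0:
        raise ValueError("K must be non-negative")
    if rho_new <= state.rho_best:
        return 0.0, 0.0, ABMDState(rho=rho_new, rho_best=rho_new)
    delta = rho_new - state.rho_best
    return 0.5 * K * delta ** 2, -K * delta, ABMDState(rho=rho_new,
                                                       rho_best=state.rho_best)


# ---------------------------------------------------------------------------
# Toy potential
# ---------------------------------------------------------------------------

@dataclass
class ToyPotential:
    """Bead-chain potential: harmonic bonds, attractive Gaussian wall sites
    (one per bead, its "starting position"), and a confining cylinder."""

    bond_k: float = 1000.0       # (kJ/mol)/nm²
    bond_r0: float = 0.38        # nm
    site_positions: Optional[np.ndarray] = None  # (n_beads, 3) nm
    site_depths: Optional[np.ndarray] = None     # kJ/mol, >= 0
    site_width: float = 0.1      # nm
    wall_radius: float = 0.5     # nm, cylinder about the x axis
    wall_k: float = 1000.0       # (kJ/mol)/nm²

    def validate(self) -> None:
        if self.site_depths is not None and np.any(self.site_depths < 0):
            raise ValueError("site depths must be non-negative")
        if self.site_width <= 0:
            raise ValueError("site width must be positive")

    def energy_forces(self, x: np.ndarray) -> Tuple[float, np.ndarray]:
        """Total energy (kJ/mol) and per-bead forces (kJ/mol/nm); x in nm."""
        n = len(x)
        f = np.zeros_like(x)
        e = 0.0
        # bonds
        for i in range(n - 1):
            d = x[i + 1] - x[i]
            r = np.linalg.norm(d)
            if r > 0:
                de = self.bond_k * (r - self.bond_r0)
                e += 0.5 * self.bond_k * (r - self.bond_r0) ** 2
                g = de * d / r
                f[i] += g
                f[i + 1] -= g
        # sticky sites
        if self.site_positions is not None and self.site_depths is not None:
            w2 = self.site_width ** 2
            for i in range(min(n, len(self.site_positions))):
                depth = self.site_depths[i]
                if depth <= 0:
                    continue
                d = x[i] - self.site_positions[i]
                g = math.exp(-float(d @ d) / (2 * w2))
                e += -depth * g
                f[i] += -depth * g * d / w2
        # confining cylinder (radial in y, z)
        r_perp = np.sqrt(x[:, 1] ** 2 + x[:, 2] ** 2)
        over = r_perp > self.wall_radius
        if np.any(over):
            excess = r_perp[over] - self.wall_radius
            e += 0.5 * self.wall_k * float(np.sum(excess ** 2))
            unit = x[over][:, 1:] / r_perp[over][:, None]
            f[over, 1:] -= self.wall_k * excess[:, None] * unit
        return e, f


# ---------------------------------------------------------------------------
# BAOAB Langevin integrator
# ---------------------------------------------------------------------------

def langevin_step(coords: np.ndarray, velocities: np.ndarray,
                  force: np.ndarray,
                  force_fn: Callable[[np.ndarray], np.ndarray],
                  dt_ps: float, temperature: float, friction: float,
                  masses: np.ndarray, rng: np.random.Generator
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One BAOAB update (kick – drift – thermostat – drift – kick).

    ``force`` is the force at ``coords`` (re-used from the previous step);
    ``force_fn`` evaluates total force (potential + bias) at new coordinates.
    Deterministic given the rng stream.  Stability requires
    ``dt < 2/ω`` with ω = sqrt(bond_k/m) (≈ 0.6 ps for the defaults).
    """
    m = masses[:, None]
    kT = KB * temperature
    v = velocities + 0.5 * dt_ps * force / m
    x = coords + 0.5 * dt_ps * v
    if friction > 0:
        c = math.exp(-friction * dt_ps)
        sigma = np.sqrt((1.0 - c * c) * kT / m)
        v = c * v + sigma * rng.standard_normal(v.shape)
    x = x + 0.5 * dt_ps * v
    new_force = force_fn(x)
    v = v + 0.5 * dt_ps * new_force / m
    return x, v, new_force


# ---------------------------------------------------------------------------
# Toy system + replica runner
# ---------------------------------------------------------------------------

@dataclass
class ToySystem:
    """Bead-chain system in the toy tunnel, ready for ABMD replicas."""

    potential: ToyPotential
    x0: np.ndarray               # (n_beads, 3) nm
    masses: np.ndarray           # amu
    temperature: float = 300.0   # K
    friction: float = 2.0        # 1/ps
    # dt must resolve the stiffest mode: sqrt((bond_k + K)/m)·dt < 1 even for
    # the K = 10^4 end of the calibration sweep
    dt: float = 5e-5             # ns
    stride: int = 100            # frames every stride steps
    residues: Optional[Sequence[int]] = None  # AP residue numbers of beads
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def topology(self) -> Topology:
        n = len(self.x0)
        residues = list(self.residues) if self.residues is not None \
            else list(range(237, 237 + n))
        names = ["CA"] * n
        entity = [Entity.AP.value] * n
        res_names = ["UNK"] * n
        seqs = residues[:]
        if self.potential.site_positions is not None:
            for k, pos in enumerate(self.potential.site_positions):
                names.append("P")
                entity.append(Entity.RIBOSOME.value)
                res_names.append("28S")
                seqs.append(3000 + k)
        topo = Topology(
            atom_id=np.arange(1, len(names) + 1),
            atom_name=np.array(names, dtype=object),
            residue_seq=np.array(seqs, dtype=int),
            residue_name=np.array(res_names, dtype=object),
            entity=np.array(entity, dtype=object),
            is_heavy=np.ones(len(names), dtype=bool),
            is_calpha=np.array([e == Entity.AP.value for e in entity]),
        )
        topo.validate()
        return topo

    def all_coords(self, x_beads: np.ndarray) -> np.ndarray:
        """Full coordinate frame (beads + static wall sites), Å."""
        parts = [x_beads]
        if self.potential.site_positions is not None:
            parts.append(self.potential.site_positions)
        return nm_to_ang(np.vstack(parts))


def default_toy_system(n_beads: int = 3, site_depth: float = 11.0,
                       target_distance: float = 4.0,
                       time_bound: float = 1.0, **kwargs) -> Tuple[ToySystem, ABMDParams]:
    """Small calibrated chain: beads anchored at sticky sites in a cylinder,
    virtual point ``target_distance`` nm down the exit axis (-x)."""
    spacing = 0.38
    x0 = np.zeros((n_beads, 3))
    x0[:, 0] = np.arange(n_beads) * spacing
    potential = ToyPotential(
        site_positions=x0.copy(),
        site_depths=np.full(n_beads, float(site_depth)),
    )
    system = ToySystem(potential=potential, x0=x0,
                       masses=np.full(n_beads, 100.0), **kwargs)
    params = ABMDParams(
        K=25.0,
        time_bound=time_bound,
        virtual_point=nm_to_ang(np.array([-target_distance, 0.0, 0.0])),
    )
    return system, params


@dataclass
class ReplicaResult:
    trajectory: Trajectory
    events: EventTable
    reached_target: bool
    time_to_target: Optional[float]  # ns
    rho_trace: np.ndarray            # CV at every recorded frame, nm


def run_replica(system: ToySystem, params: ABMDParams, seed: int,
                variant: str = "toy", replica_id: int = 0) -> ReplicaResult:
    """Run one ABMD replica until arrival (CV within tolerance of the target)
    or the time bound; time-bound censoring is a normal outcome."""
    params.validate()
    system.potential.validate()
    if params.virtual_point is None:
        raise ValueError("params.virtual_point is required")
    point_nm = ang_to_nm(np.asarray(params.virtual_point, dtype=float))

    rng = np.random.default_rng(seed)
    dt_ps = system.dt * PS_PER_NS
    n_steps = int(round(params.time_bound / system.dt))
    masses = np.asarray(system.masses, dtype=float)

    x = system.x0.copy()
    kT = KB * system.temperature
    v = rng.standard_normal(x.shape) * np.sqrt(kT / masses[:, None])

    state = ABMDState(rho=float(np.linalg.norm(x[0] - point_nm)),
                      rho_best=float(np.linalg.norm(x[0] - point_nm)))
    bias_force_beads = np.zeros_like(x)

    def total_force(coords: np.ndarray) -> np.ndarray:
        _, f = system.potential.energy_forces(coords)
        return f + bias_force_beads

    frames: List[np.ndarray] = []
    times: List[float] = []
    rhos: List[float] = []
    reached = False
    t_reach: Optional[float] = None

    force = total_force(x)
    for step in range(n_steps + 1):
        t_ns = step * system.dt
        rho = float(np.linalg.norm(x[0] - point_nm))
        _, f_cv, state = abmd_update(state, rho, params.K)
        # chain rule: generalised CV force acts on the N-terminal bead along
        # the unit vector from the virtual point to the bead
        if rho > 0:
            bias_force_beads[0] = f_cv * (x[0] - point_nm) / rho
        else:
            bias_force_beads[0] = 0.0

        if step % system.stride == 0:
            frames.append(system.all_coords(x))
            times.append(t_ns)
            rhos.append(rho)
        if rho <= params.cv_target + params.arrival_tol:
            reached = True
            t_reach = t_ns
            if step % system.stride != 0:
                frames.append(system.all_coords(x))
                times.append(t_ns)
                rhos.append(rho)
            break
        if step == n_steps:
            break
        x, v, force = langevin_step(x, v, force, total_force, dt_ps,
                                    system.temperature, system.friction,
                                    masses, rng)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite coordinates at step {step + 1}")

    topo = system.topology()
    traj = Trajectory(topo, np.array(times), np.array(frames),
                      replica_id=replica_id, variant=variant)
    traj.validate()

    from .kinetics import events_from_trajectory

    events = events_from_trajectory(traj, analysis=system.analysis,
                                    virtual_point=np.asarray(params.virtual_point))
    return ReplicaResult(trajectory=traj, events=events, reached_target=reached,
                         time_to_target=t_reach, rho_trace=np.array(rhos))


def spring_sweep(system: ToySystem, K_values: Sequence[float],
                 n_replicas: int = 20, seed: int = 0,
                 time_bound: Optional[float] = None,
                 params: Optional[ABMDParams] = None) -> pd.DataFrame:
    """Spring-constant calibration sweep.

    The same per-replica seeds are reused for every K (common random
    numbers), so duplicate K values give identical summaries.  Censored
    times enter the time-to-target mean at the bound value (documented
    convention for the monotonicity diagnostic).
    """
    if len(K_values) < 2:
        raise ValueError("sweep needs at least 2 K values")
    from .synth import child_seeds

    base = params or ABMDParams(
        virtual_point=nm_to_ang(np.array([-2.0, 0.0, 0.0])))
    seeds = child_seeds(seed, n_replicas)
    rows = []
    for K in K_values:
        p = replace(base, K=float(K))
        if time_bound is not None:
            p = replace(p, time_bound=time_bound)
        detach, extraction, t_target = [], [], []
        n_exited = 0
        n_reached = 0
        for i, s in enumerate(seeds):
            res = run_replica(system, p, s, replica_id=i)
            detach.append(res.events.t_detach_M260)
            extraction.append(res.events.extraction_time_T)
            n_exited += int(res.events.exited)
            n_reached += int(res.reached_target)
            t_target.append(res.time_to_target if res.time_to_target is not None
                            else p.time_bound)
        def _mean(vals):
            vals = [v for v in vals if v is not None]
            return float(np.mean(vals)) if vals else math.nan
        rows.append({
            "K": float(K),
            "mean_detach_ns": _mean(detach),
            "mean_extraction_ns": _mean(extraction),
            "n_exited": n_exited,
            "n_reached": n_reached,
            "mean_time_to_target_ns": float(np.mean(t_target)),
        })
    return pd.DataFrame(rows)
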