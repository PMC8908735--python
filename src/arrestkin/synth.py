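"""Synthetic replica ensembles and the coordinate-level renderer.

The event model draws per-residue residence times as independent Gamma
increments (sequential N->C release), censors at the time bound, and adds
the extraction observables.  :func:`render_trajectory` turns an event table
into a 3D bead trajectory inside a toy cylindrical exit tunnel with sticky
wall sites, built so that the kinetics module recovers every event time
within one frame interval (the pipeline's central round-trip oracle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    AP_RESIDUES,
    AP_SEQUENCE,
    AnalysisConfig,
    Entity,
    EventTable,
    Topology,
    Trajectory,
    VariantConfig,
)
from .io import read_variant_configs
from .units import nm_to_ang

#: Canonical variant names in stalling-experiment order.
VARIANT_NAMES = ("WT", "S255A", "W256A", "C247K/S255A", "C247S/P254C/S255A")


def default_variant_configs() -> Dict[str, VariantConfig]:
    """Packaged default configurations for the five AP variants."""
    with resources.as_file(
        resources.files("arrestkin").joinpath("data/variants.yaml")
    ) as path:
        return read_variant_configs(path)


def child_seeds(master_seed: int, n: int) -> List[int]:
    """Fixed master-seed -> replica-seed splitting rule (recorded in manifests)."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2 ** 31) for s in state]


# ---------------------------------------------------------------------------
# Event sampling
# ---------------------------------------------------------------------------

def sample_event_table(config: VariantConfig, seed: int, replica: int = 0,
                       cv_target_nm: float = 12.5) -> EventTable:
    """Draw one replica: sequential Gamma release chain plus extraction draws.

    Release times are the cumulative sum of independent Gamma increments with
    per-residue mean ``residence_mean[i]`` and shape ``residence_shape``
    (``shape = inf`` is the deterministic limit).  A residue with infinite
    mean censors itself and everything C-ward; any release past the censor
    bound is censored likewise.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    means = np.array([config.residence_mean[r] for r in AP_RESIDUES], dtype=float)

    increments = np.empty_like(means)
    finite = np.isfinite(means) & (means > 0)
    increments[means == 0] = 0.0
    increments[~np.isfinite(means)] = math.inf
    if math.isinf(config.residence_shape):
        increments[finite] = means[finite]
    else:
        shape = config.residence_shape
        increments[finite] = rng.gamma(shape, means[finite] / shape)

    cumulative = np.cumsum(increments)
    censored = ~np.isfinite(cumulative) | (cumulative > config.censor_time)
    # censoring is monotone C-ward by construction (cumulative sums)
    t_release: Dict[int, Optional[float]] = {
        res: (None if c else float(t))
        for res, t, c in zip(AP_RESIDUES, cumulative, censored)
    }

    t_detach = t_release[AP_RESIDUES[-1]]
    exited = False
    extraction: Optional[float] = None
    if t_detach is not None:
        exited = bool(rng.random() < config.exit_probability)
        if exited:
            if not math.isfinite(config.extraction_mean):
                raise ValueError("exited replica needs a finite extraction_mean")
            extraction = float(rng.gamma(
                config.extraction_shape,
                config.extraction_mean / config.extraction_shape,
            ))

    if exited:
        covered = cv_target_nm
    else:
        fraction = sum(v is not None for v in t_release.values()) / len(AP_RESIDUES)
        covered = cv_target_nm * fraction * config.partial_exit_scale

    table = EventTable(
        variant=config.name,
        replica=replica,
        t_release=t_release,
        t_detach_M260=t_detach,
        t_release_L259=t_release[259],
        extraction_time_T=extraction,
        exited=exited,
        covered_distance_D=covered,
    )
    table.validate(censor_time=config.censor_time)
    return table


def sample_ensemble(config: VariantConfig, master_seed: int,
                    n_replicas: Optional[int] = None,
                    cv_target_nm: float = 12.5) -> List[EventTable]:
    """Draw ``n_replicas`` event tables from per-replica child seeds."""
    n = config.n_replicas if n_replicas is None else n_replicas
    return [
        sample_event_table(config, s, replica=i, cv_target_nm=cv_target_nm)
        for i, s in enumerate(child_seeds(master_seed, n))
    ]


# ---------------------------------------------------------------------------
# Toy tunnel geometry
# ---------------------------------------------------------------------------

@dataclass
class TunnelModel:
    """Abstract cylindrical exit tunnel with sticky interaction sites.

    The tunnel axis is x; residue 237 anchors at the origin (nearest the
    exit) and the chain extends in +x toward the PTC.  Extraction proceeds
    in -x.  Wall sites sit on a ring of radius ``wall_radius`` around the
    axis; a contiguous lining (spacing ``spacing/2``) keeps any bead on the
    axis within the contact cutoff until it passes the tunnel mouth.
    """

    spacing: float = 3.8        # Å between consecutive residue anchors
    wall_radius: float = 3.2    # Å radial offset of wall sites
    release_jump: float = 4.2   # Å instantaneous displacement at release
    #: wall sites: (position Å, entity, residue_seq, residue_name, atom_name)
    wall_sites: List[Tuple[np.ndarray, Entity, int, str, str]] = field(
        default_factory=list)
    site_anchor: Dict[int, int] = field(default_factory=dict)
    ap_residues: Tuple[int, ...] = AP_RESIDUES

    @property
    def axis(self) -> np.ndarray:
        return np.array([-1.0, 0.0, 0.0])  # direction of extraction

    @property
    def length(self) -> float:
        return (len(self.ap_residues) - 1) * self.spacing + self.spacing

    def anchor_position(self, residue: int) -> np.ndarray:
        k = residue - self.ap_residues[0]
        return np.array([k * self.spacing, 0.0, 0.0])

    @property
    def mouth_x(self) -> float:
        return -self.spacing

    def clearance_x(self, contact_cutoff: float = 3.5) -> float:
        """x below which a bead on the axis is out of reach of every wall site."""
        reach = math.sqrt(max(contact_cutoff ** 2 - self.wall_radius ** 2, 0.0))
        return self.mouth_x - reach

    def virtual_point(self, cv_target_nm: float = 12.5) -> np.ndarray:
        """CV target: fixed point beyond the mouth on the tunnel axis."""
        return np.array([-nm_to_ang(cv_target_nm), 0.0, 0.0])


def default_tunnel(region_sites: Optional[Dict[str, int]] = None) -> TunnelModel:
    """Build the packaged tunnel.

    ``region_sites`` gives the number of wall sites ringing each anchored
    residue per region (default NT:1, I:2, CT:3 — the C-terminal residues
    of a stalled chain see the most persistent tunnel contacts).  A P-tRNA
    pseudo-nucleobase (A76) sits next to the Leu259 anchor.
    """
    from .core import RegionMap

    region_sites = region_sites or {"NT": 1, "I": 2, "CT": 3}
    tunnel = TunnelModel()
    regions = RegionMap()
    seq = 3000
    r = tunnel.wall_radius

    # contiguous lining along the tunnel (half-spacing grid, +y side)
    x0 = tunnel.mouth_x
    x1 = tunnel.anchor_position(AP_RESIDUES[-1])[0]
    n_l = int(round((x1 - x0) / (tunnel.spacing / 2))) + 1
    for k in range(n_l):
        x = x0 + k * tunnel.spacing / 2
        tunnel.wall_sites.append(
            (np.array([x, r, 0.0]), Entity.RIBOSOME, seq, "28S", "P"))
        seq += 1

    # per-residue anchor rings; site 0 of each ring is the residue's anchor site
    angles = [0.0, 2 * math.pi / 3, 4 * math.pi / 3]
    for res in AP_RESIDUES:
        n_sites = region_sites[regions.region_of(res)]
        x = tunnel.anchor_position(res)[0]
        for j in range(n_sites):
            pos = np.array([x, r * math.cos(angles[j]), r * math.sin(angles[j])])
            if j == 0:
                # the +y anchor ring site coincides with a lining site; keep the
                # lining site as the anchor to avoid duplicated positions
                tunnel.site_anchor[res] = next(
                    i for i, s in enumerate(tunnel.wall_sites)
                    if abs(s[0][0] - x) < 1e-9 and s[0][1] == r and s[0][2] == 0.0
                )
                continue
            tunnel.wall_sites.append(
                (pos, Entity.RIBOSOME, seq, "28S", "P"))
            seq += 1

    # P-tRNA A76 proxy next to the Leu259 anchor (off-ring, -z side)
    x259 = tunnel.anchor_position(259)[0]
    tunnel.wall_sites.append(
        (np.array([x259, 0.0, -r]), Entity.P_TRNA, 76, "A", "N1"))
    return tunnel


def tunnel_topology(tunnel: TunnelModel) -> Topology:
    """Topology of 24 AP beads (one CA pseudo-atom per residue) plus wall sites."""
    names, res_seq, res_name, entity, heavy, calpha = [], [], [], [], [], []
    for res in tunnel.ap_residues:
        names.append("CA")
        res_seq.append(res)
        res_name.append(AP_SEQUENCE.get(res, "UNK"))
        entity.append(Entity.AP.value)
        heavy.append(True)
        calpha.append(True)
    for pos, ent, seq, rname, aname in tunnel.wall_sites:
        names.append(aname)
        res_seq.append(seq)
        res_name.append(rname)
        entity.append(ent.value)
        heavy.append(True)
        calpha.append(False)
    topo = Topology(
        atom_id=np.arange(1, len(names) + 1),
        atom_name=np.array(names, dtype=object),
        residue_seq=np.array(res_seq, dtype=int),
        residue_name=np.array(res_name, dtype=object),
        entity=np.array(entity, dtype=object),
        is_heavy=np.array(heavy, dtype=bool),
        is_calpha=np.array(calpha, dtype=bool),
    )
    topo.validate()
    return topo


# ---------------------------------------------------------------------------
# Renderer
# ---------------------------------------------------------------------------

DEFAULT_TRAVEL_SPEED = 1.9  # Å/ns inside the tunnel for non-exited replicas


def render_trajectory(events: EventTable, tunnel: Optional[TunnelModel] = None,
                      dt: float = 0.5,
                      analysis: Optional[AnalysisConfig] = None,
                      horizon: Optional[float] = None) -> Trajectory:
    """Render an event table as a bead trajectory in the toy tunnel.

    Contracts (all used as oracles by the test suite):

    * an anchored bead stays exactly at its anchor, within the contact
      cutoff of its wall site;
    * at its release time a bead jumps ``release_jump`` (> both displacement
      thresholds) down the axis and then travels at constant speed, so the
      kinetics module recovers each release time within one frame;
    * for an exited replica the travel speed is set so the C-terminal bead
      loses its last wall contact exactly ``extraction_time_T`` after the
      Met260 detach time, and the N-terminal bead parks on the CV target
      point (covered distance = the full CV span);
    * for a non-exited replica the released beads park just inside the
      mouth (still in wall contact), except the N-terminal bead, which
      parks at the partial covered distance recorded in the event table.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tunnel = tunnel or default_tunnel()
    analysis = analysis or AnalysisConfig()

    releases = events.t_release
    release_times = [t for t in releases.values() if t is not None]
    x_clear = tunnel.clearance_x(analysis.contact_cutoff)
    jump = tunnel.release_jump
    last_res = tunnel.ap_residues[-1]
    first_res = tunnel.ap_residues[0]
    x_last = tunnel.anchor_position(last_res)[0]
    point = tunnel.virtual_point(analysis.cv_target_distance)

    if events.exited:
        if events.extraction_time_T is None or events.t_detach_M260 is None:
            raise ValueError("exited event table lacks extraction observables")
        # C-terminal bead clears the mouth exactly T after its release
        speed = (x_last - jump - x_clear) / events.extraction_time_T
    else:
        speed = DEFAULT_TRAVEL_SPEED

    park: Dict[int, float] = {}
    for res in tunnel.ap_residues:
        if releases[res] is None:
            continue
        if res == first_res:
            park[res] = -nm_to_ang(events.covered_distance_D)
        elif events.exited:
            park[res] = point[0] + (res - first_res) * tunnel.spacing
        else:
            park[res] = tunnel.mouth_x
    # a bead can never park short of its post-release position
    for res, x_p in park.items():
        x_jumped = tunnel.anchor_position(res)[0] - jump
        park[res] = min(x_p, x_jumped)

    def position(res: int, t: float) -> np.ndarray:
        anchor = tunnel.anchor_position(res)
        tau = releases[res]
        if tau is None or t < tau:
            return anchor
        x = anchor[0] - jump - speed * (t - tau)
        return np.array([max(x, park[res]), 0.0, 0.0])

    if horizon is None:
        horizon = 5.0
        if release_times:
            horizon = max(release_times) + 2 * dt
            arrivals = [
                releases[res] + (tunnel.anchor_position(res)[0] - jump
                                 - park[res]) / speed
                for res in park
            ]
            horizon = max([horizon] + arrivals) + 2 * dt

    topo = tunnel_topology(tunnel)
    n_frames = int(math.floor(horizon / dt)) + 1
    times = np.arange(n_frames) * dt
    n_ap = len(tunnel.ap_residues)
    coords = np.empty((n_frames, topo.n_atoms, 3))
    wall_coords = np.array([s[0] for s in tunnel.wall_sites])
    for k, t in enumerate(times):
        for j, res in enumerate(tunnel.ap_residues):
            coords[k, j] = position(res, float(t))
        coords[k, n_ap:] = wall_coords

    traj = Trajectory(topo, times, coords,
                      replica_id=events.replica, variant=events.variant)
    traj.validate()
    return traj
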