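"""First-passage release kinetics: the five extraction metrics, per-residue
kinetic signatures, ensemble statistics and variant ranking.

Times are ns; a ``None`` return means the event was censored (did not occur
within the trajectory / the time bound).  Censored values never enter a
mean; every mean is reported with the number of contributing replicas.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sps

from .core import (
    AP_RESIDUES,
    AnalysisConfig,
    Entity,
    EventTable,
    RIBOSOME_COMPLEX,
    Trajectory,
)
from .units import ang_to_nm


# ---------------------------------------------------------------------------
# Trajectory-level first-passage metrics
# ---------------------------------------------------------------------------

def _residue_reference_positions(traj: Trajectory, residue: int,
                                 mode: str) -> np.ndarray:
    """Per-frame position of the residue marker (Cα atom or heavy-atom centroid)."""
    topo = traj.topology
    if mode.upper() == "CALPHA":
        mask = topo.ap_mask & (topo.residue_seq == residue) & topo.is_calpha
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"residue {residue} has no C-alpha atom")
        return traj.coords[:, idx[0], :]
    if mode.upper() == "COM":
        idx = topo.ap_residue_atoms(residue, heavy_only=True)
        return traj.coords[:, idx, :].mean(axis=1)
    raise ValueError(f"unknown mode {mode!r}")


def first_displacement_time(traj: Trajectory, residue: int,
                            threshold: float = 3.5,
                            mode: str = "CALPHA") -> Optional[float]:
    """Earliest frame time at which the residue marker has moved strictly
    more than ``threshold`` Å from its frame-0 position; ``None`` if never."""
    pos = _residue_reference_positions(traj, residue, mode)
    disp = np.linalg.norm(pos - pos[0], axis=1)
    hits = np.flatnonzero(disp > threshold)
    return float(traj.times[hits[0]]) if hits.size else None


def _min_distance_series(traj: Trajectory, mask_a: np.ndarray,
                         mask_b: np.ndarray) -> np.ndarray:
    """Per-frame minimum heavy-atom distance between two atom groups."""
    ia = np.flatnonzero(mask_a)
    ib = np.flatnonzero(mask_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("empty atom group")
    a = traj.coords[:, ia, :]
    b = traj.coords[:, ib, :]
    d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1)
    return d.reshape(traj.n_frames, -1).min(axis=1)


def ptc_detach_time(source: Union[Trajectory, EventTable],
                    threshold: float = 3.8) -> Optional[float]:
    """Metric 1: first time the C-terminal residue (Met260) is displaced
    more than ``threshold`` (default 3.8 Å) from its original position."""
    if isinstance(source, EventTable):
        return source.t_detach_M260
    residue = max(source.topology.ap_residues)
    return first_displacement_time(source, residue, threshold=threshold)


def leu259_release_time(traj: Trajectory, cutoff: float = 3.5,
                        residue: int = 259) -> Optional[float]:
    """First time Leu259 moves > ``cutoff`` from the P-tRNA A76 nucleobase
    (the translation-resumption proxy); ``None`` if the contact never breaks."""
    topo = traj.topology
    mask_a = topo.ap_mask & (topo.residue_seq == residue) & topo.is_heavy
    mask_b = topo.entity_mask(Entity.P_TRNA) & topo.is_heavy
    if not mask_b.any():
        raise ValueError("topology has no P-tRNA atoms")
    dmin = _min_distance_series(traj, mask_a, mask_b)
    hits = np.flatnonzero(dmin > cutoff)
    return float(traj.times[hits[0]]) if hits.size else None


def extraction_time(source: Union[Trajectory, EventTable],
                    cutoff: float = 3.5,
                    detach_threshold: float = 3.8) -> Optional[float]:
    """Metric 3: time from PTC detachment until no AP atom is within
    ``cutoff`` of any ribosome-complex atom.  Censored detach implies a
    censored extraction."""
    if isinstance(source, EventTable):
        return source.extraction_time_T
    detach = ptc_detach_time(source, threshold=detach_threshold)
    if detach is None:
        return None
    topo = source.topology
    mask_ap = topo.ap_mask & topo.is_heavy
    mask_rib = topo.entity_mask(*RIBOSOME_COMPLEX) & topo.is_heavy
    dmin = _min_distance_series(source, mask_ap, mask_rib)
    hits = np.flatnonzero(dmin > cutoff)
    if hits.size == 0:
        return None
    return float(source.times[hits[0]]) - detach


def cv_series(traj: Trajectory, virtual_point: np.ndarray) -> np.ndarray:
    """Per-frame CV (nm): N-terminal residue heavy-atom COM to the fixed point."""
    from .abmd import cv_value

    residue = min(traj.topology.ap_residues)
    return np.array([
        cv_value(traj.coords[k], traj.topology, virtual_point, residue=residue)
        for k in range(traj.n_frames)
    ])


def covered_distance(traj: Trajectory, virtual_point: np.ndarray) -> float:
    """Metric 5: CV(first frame) − CV(last frame), nm."""
    cv = cv_series(traj, virtual_point)
    return float(cv[0] - cv[-1])


def events_from_trajectory(traj: Trajectory,
                           analysis: Optional[AnalysisConfig] = None,
                           virtual_point: Optional[np.ndarray] = None,
                           mode: str = "CALPHA") -> EventTable:
    """Apply all five metrics to a trajectory and assemble an event table."""
    analysis = analysis or AnalysisConfig()
    releases = {
        res: first_displacement_time(
            traj, res, threshold=analysis.displacement_threshold, mode=mode)
        for res in traj.topology.ap_residues
    }
    detach = ptc_detach_time(traj, threshold=analysis.ptc_detach_threshold)
    extraction = extraction_time(
        traj, cutoff=analysis.contact_cutoff,
        detach_threshold=analysis.ptc_detach_threshold)
    covered = 0.0
    if virtual_point is not None:
        covered = covered_distance(traj, virtual_point)
    return EventTable(
        variant=traj.variant,
        replica=traj.replica_id,
        t_release=releases,
        t_detach_M260=detach,
        t_release_L259=releases.get(259),
        extraction_time_T=extraction,
        exited=extraction is not None,
        covered_distance_D=covered,
    )


# ---------------------------------------------------------------------------
# Ensemble statistics
# ---------------------------------------------------------------------------

def _mean_se(values: Sequence[float]) -> Tuple[Optional[float], Optional[float], int]:
    """Mean and SE = SD/sqrt(n) over uncensored values (ddof=1)."""
    vals = [v for v in values if v is not None]
    n = len(vals)
    if n == 0:
        return None, None, 0
    mean = float(np.mean(vals))
    se = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return mean, se, n


@dataclass
class VariantKinetics:
    """Ensemble-averaged kinetic signature and Table-1-style observables."""

    variant: str
    n_replicas: int
    t_profile: Dict[int, Tuple[Optional[float], Optional[float], int]]
    dt_profile: Dict[int, Tuple[Optional[float], Optional[float]]]
    t_M260: Tuple[Optional[float], Optional[float]]
    t_L259: Tuple[Optional[float], Optional[float]]
    T_extraction: Tuple[Optional[float], Optional[float]]
    n_detached: int
    n_exited: int
    D_mean: Tuple[Optional[float], Optional[float]]
    f_L: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "n_replicas": self.n_replicas,
            "t_profile": {r: list(v) for r, v in self.t_profile.items()},
            "dt_profile": {r: list(v) for r, v in self.dt_profile.items()},
            "t_M260": list(self.t_M260),
            "t_L259": list(self.t_L259),
            "T_extraction": list(self.T_extraction),
            "n_detached": self.n_detached,
            "n_exited": self.n_exited,
            "D_mean": list(self.D_mean),
            "f_L": self.f_L,
        }


def delta_profile(table: EventTable) -> Dict[int, Optional[float]]:
    """Per-replica residence increments Δt^i = t^i − t^(i−1) (Δ at the first
    residue is its release time).  Negative increments in user data are
    reported as-is with a warning, never clipped."""
    residues = table.residues
    deltas: Dict[int, Optional[float]] = {}
    prev: Optional[float] = 0.0
    for res in residues:
        t = table.t_release[res]
        if t is None or prev is None:
            deltas[res] = None
        else:
            d = t - prev
            if d < 0:
                warnings.warn(
                    f"negative residence increment at residue {res} "
                    f"(release-order inversion)", RuntimeWarning)
            deltas[res] = d
        prev = t
    return deltas


def ensemble_profile(tables: Sequence[EventTable],
                     f_L: Optional[float] = None) -> VariantKinetics:
    """Ensemble means/SEs over uncensored replicas.

    The Δ profile is the finite difference of the mean release-time profile
    (difference of means); the per-replica variant is available through
    :func:`delta_profile`.  Censored replicas count in the detach/exit
    denominators but never in a time mean.
    """
    if len(tables) < 2:
        raise ValueError("ensemble statistics need at least 2 replicas")
    variants = {t.variant for t in tables}
    if len(variants) > 1:
        raise ValueError(f"mixed variants in one ensemble: {sorted(variants)}")

    residues = tables[0].residues
    t_profile = {}
    for res in residues:
        t_profile[res] = _mean_se([t.t_release[res] for t in tables])

    dt_profile: Dict[int, Tuple[Optional[float], Optional[float]]] = {}
    prev_mean, prev_se = 0.0, 0.0
    for res in residues:
        mean, se, n = t_profile[res]
        if mean is None or prev_mean is None:
            dt_profile[res] = (None, None)
        else:
            dt_profile[res] = (
                mean - prev_mean,
                math.sqrt((se or 0.0) ** 2 + (prev_se or 0.0) ** 2),
            )
        prev_mean, prev_se = mean, se

    m260, se260, n_det = _mean_se([t.t_detach_M260 for t in tables])
    m259, se259, _ = _mean_se([t.t_release_L259 for t in tables])
    mT, seT, n_T = _mean_se(
        [t.extraction_time_T for t in tables if t.exited])
    mD, seD, _ = _mean_se([t.covered_distance_D for t in tables])

    return VariantKinetics(
        variant=tables[0].variant,
        n_replicas=len(tables),
        t_profile=t_profile,
        dt_profile=dt_profile,
        t_M260=(m260, se260),
        t_L259=(m259, se259),
        T_extraction=(mT, seT),
        n_detached=sum(1 for t in tables if t.detached),
        n_exited=sum(1 for t in tables if t.exited),
        D_mean=(mD, seD),
        f_L=f_L,
    )


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

@dataclass
class VariantRanking:
    """Stalling-strength order (strongest first) with tie flags and the
    Spearman concordance against the experimental (1 − f_L) readout."""

    order: List[str]
    ties: List[Tuple[str, str]]
    spearman: Optional[float]


def rank_variants(kinetics: Sequence[VariantKinetics]) -> VariantRanking:
    """Sort variants by stalling strength.

    Fully censored detachment (no replica detaches) ranks strongest; the
    rest sort by descending mean Met260 detach time.  Pairs whose detach
    means differ by less than one combined SE are flagged as "≈" ties.
    """
    if len(kinetics) < 2:
        raise ValueError("ranking needs at least 2 variants")

    def key(vk: VariantKinetics):
        mean = vk.t_M260[0]
        censored = vk.n_detached == 0
        return (0 if censored else 1, -(mean if mean is not None else 0.0))

    ordered = sorted(kinetics, key=key)
    ties = []
    for a, b in zip(ordered, ordered[1:]):
        ma, sa = a.t_M260
        mb, sb = b.t_M260
        if ma is None or mb is None:
            continue
        if abs(ma - mb) <= (sa or 0.0) + (sb or 0.0):
            ties.append((a.variant, b.variant))

    spearman = None
    if all(vk.f_L is not None for vk in kinetics):
        strength_rank = {vk.variant: i for i, vk in enumerate(ordered[::-1])}
        xs = [strength_rank[vk.variant] for vk in kinetics]
        ys = [1.0 - vk.f_L for vk in kinetics]
        rho = sps.spearmanr(xs, ys).statistic
        spearman = float(rho) if np.isfinite(rho) else None

    return VariantRanking(
        order=[vk.variant for vk in ordered],
        ties=ties,
        spearman=spearman,
    )
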