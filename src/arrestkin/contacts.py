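"""Contact detection, persistence filtering, network tracking and RMSD.

A contact is a heavy-atom pair within the distance cutoff (default 3.5 Å,
ties count as in contact); hydrogen bonds and hydrophobic interactions are
pooled under this single criterion, with no angular terms and no hysteresis
(a contact is lost the moment the distance exceeds the same cutoff).
Intramolecular AP contacts exclude bonded neighbours (|i−j| <= 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .core import Entity, RegionMap, Topology, Trajectory

#: The three interconnected intramolecular AP contact networks.
CONTACT_NETWORKS: Dict[str, FrozenSet[int]] = {
    "CN1": frozenset({247, 248, 249}),
    "CN2": frozenset({251, 254, 255, 257}),
    "CN3": frozenset({250, 253, 256}),
}

#: (entity, residue_seq, residue_name) identifying a contact partner.
Partner = Tuple[str, int, str]
#: (kind, ap_residue, partner) — kind is "INTER" or "INTRA".
ContactPair = Tuple[str, int, Partner]


@dataclass(frozen=True)
class ContactRecord:
    ap_residue: int
    partner: Partner
    kind: str  # INTER | INTRA
    persistence: float


def min_heavy_distance(frame: np.ndarray, group_a: Sequence[int],
                       group_b: Sequence[int]) -> float:
    """Minimum pairwise Euclidean distance (Å) between two disjoint atom sets."""
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty atom group")
    if np.intersect1d(a, b).size:
        raise ValueError("atom groups must be disjoint")
    return float(cdist(frame[a], frame[b]).min())


def _heavy_residue_labels(topology: Topology):
    """Heavy-atom indices with per-atom residue labels used for grouping."""
    heavy = np.flatnonzero(topology.is_heavy)
    labels = [
        (topology.entity[i], int(topology.residue_seq[i]),
         str(topology.residue_name[i]))
        for i in heavy
    ]
    return heavy, labels


def contacts_in_frame(frame: np.ndarray, topology: Topology,
                      cutoff: float = 3.5,
                      brute_force: bool = False) -> Set[ContactPair]:
    """All INTER (AP↔other entity) and INTRA (AP↔AP, |i−j| >= 2) residue
    contacts in one frame; a pair is in contact iff its minimum heavy-atom
    distance is <= cutoff.

    The default path uses a k-d tree; ``brute_force=True`` runs the
    all-pairs double loop (the oracle the tree path is tested against).
    """
    heavy, labels = _heavy_residue_labels(topology)
    coords = frame[heavy]
    is_ap = topology.entity[heavy] == Entity.AP.value

    if brute_force:
        d = cdist(coords, coords)
        ii, jj = np.nonzero(d <= cutoff)
        pairs = [(int(i), int(j)) for i, j in zip(ii, jj) if i < j]
    else:
        tree = cKDTree(coords)
        pairs = [(int(i), int(j)) for i, j in tree.query_pairs(cutoff)]

    out: Set[ContactPair] = set()
    for i, j in pairs:
        if is_ap[i] and is_ap[j]:
            ri, rj = labels[i][1], labels[j][1]
            if abs(ri - rj) <= 1:
                continue
            lo, hi = sorted((i, j), key=lambda k: labels[k][1])
            out.add(("INTRA", labels[lo][1],
                     (str(labels[hi][0]), labels[hi][1], labels[hi][2])))
        elif is_ap[i] or is_ap[j]:
            ap, other = (i, j) if is_ap[i] else (j, i)
            out.add(("INTER", labels[ap][1],
                     (str(labels[other][0]), labels[other][1], labels[other][2])))
    return out


def persistence_table(traj: Trajectory, cutoff: float = 3.5) -> List[ContactRecord]:
    """Persistence (fraction of frames present) for every residue pair that
    is ever in contact along the trajectory."""
    if traj.n_frames < 2:
        raise ValueError("persistence needs at least 2 frames")
    counts: Dict[ContactPair, int] = {}
    for k in range(traj.n_frames):
        for pair in contacts_in_frame(traj.coords[k], traj.topology, cutoff):
            counts[pair] = counts.get(pair, 0) + 1
    return [
        ContactRecord(ap_residue=res, partner=partner, kind=kind,
                      persistence=n / traj.n_frames)
        for (kind, res, partner), n in sorted(counts.items())
    ]


def filter_persistent(records: Iterable[ContactRecord],
                      threshold: float) -> List[ContactRecord]:
    return [r for r in records if r.persistence >= threshold]


def persistent_counts_by_residue(records: Sequence[ContactRecord],
                                 region_map: Optional[RegionMap] = None,
                                 thresholds: Sequence[float] = (0.5, 0.75),
                                 ) -> pd.DataFrame:
    """Per-residue counts of persistent INTER and INTRA contacts at each
    persistence threshold, annotated with the NT/I/CT region."""
    region_map = region_map or RegionMap()
    residues = sorted({r.ap_residue for r in records})
    lo, hi = region_map.nt[0], region_map.ct[1]
    residues = sorted(set(residues) | set(range(lo, hi + 1)))
    rows = []
    for res in residues:
        row = {"residue": res, "region": region_map.region_of(res)}
        for thr in thresholds:
            kept = filter_persistent(records, thr)
            for kind in ("INTER", "INTRA"):
                row[f"{kind.lower()}_{int(round(thr * 100))}"] = sum(
                    1 for r in kept if r.ap_residue == res and r.kind == kind)
        rows.append(row)
    return pd.DataFrame(rows).set_index("residue")


def network_timeseries(traj: Trajectory,
                       networks: Optional[Dict[str, FrozenSet[int]]] = None,
                       cutoff: float = 3.5) -> pd.DataFrame:
    """Per-frame intactness of each contact network.

    A network is intact in a frame iff every member residue is within the
    cutoff (minimum heavy-atom distance) of at least one other member at
    sequence separation |i−j| >= 2.
    """
    networks = networks or CONTACT_NETWORKS
    topo = traj.topology
    member_atoms: Dict[int, np.ndarray] = {}
    for members in networks.values():
        for res in members:
            if res not in member_atoms:
                member_atoms[res] = topo.ap_residue_atoms(res, heavy_only=True)
    data = {}
    for name, members in networks.items():
        ok = np.ones(traj.n_frames, dtype=bool)
        for res in members:
            partners = [m for m in members if abs(m - res) >= 2]
            if not partners:
                ok[:] = False
                break
            near = np.zeros(traj.n_frames, dtype=bool)
            for other in partners:
                a = traj.coords[:, member_atoms[res], :]
                b = traj.coords[:, member_atoms[other], :]
                d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1)
                near |= d.reshape(traj.n_frames, -1).min(axis=1) <= cutoff
            ok &= near
        data[name] = ok
    return pd.DataFrame(data, index=traj.times)


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def kabsch_rmsd(coords: np.ndarray, reference: np.ndarray) -> float:
    """Optimal-superposition RMSD between two matched coordinate sets (Å)."""
    if coords.shape != reference.shape:
        raise ValueError("coordinate sets must have matching shapes")
    x = coords - coords.mean(axis=0)
    y = reference - reference.mean(axis=0)
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    s_corr = s.copy()
    s_corr[-1] *= sign
    n = len(x)
    msd = (np.sum(x ** 2) + np.sum(y ** 2) - 2.0 * s_corr.sum()) / n
    return float(math.sqrt(max(msd, 0.0)))


def rmsd_to_reference(traj: Trajectory, reference: np.ndarray,
                      atom_indices: Sequence[int]) -> np.ndarray:
    """Per-frame Kabsch RMSD to a reference frame over an atom selection."""
    idx = np.asarray(atom_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty atom selection")
    if reference.shape[0] != traj.coords.shape[1]:
        raise ValueError("reference frame does not match trajectory atoms")
    ref = reference[idx]
    return np.array([
        kabsch_rmsd(traj.coords[k, idx, :], ref) for k in range(traj.n_frames)
    ])
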