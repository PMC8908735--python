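"""Core domain types shared by every stage of the pipeline.

Conventions
-----------
* Coordinates and distance cutoffs are in angstrom (Å).
* The pulling collective variable (CV) and the covered distance are
  reported in nanometres; conversion is centralised in :mod:`arrestkin.units`.
* Times are in nanoseconds throughout.
* A censored observation (the event did not occur before the time bound)
  is represented as ``None``, never as a sentinel number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

AP_RESIDUE_RANGE: Tuple[int, int] = (237, 260)
#: Residue numbers of the 24-residue arrest peptide, N- to C-terminus.
AP_RESIDUES: Tuple[int, ...] = tuple(range(237, 261))

#: One-letter-derived 3-letter names of the wild-type XBP1u arrest peptide,
#: residues 237-260 (DPVPYQPPFLCQWGRHQPSWKPLM).
AP_SEQUENCE: Dict[int, str] = dict(
    zip(
        AP_RESIDUES,
        [
            "ASP", "PRO", "VAL", "PRO", "TYR", "GLN", "PRO", "PRO",
            "PHE", "LEU", "CYS", "GLN", "TRP", "GLY", "ARG", "HIS",
            "GLN", "PRO", "SER", "TRP", "LYS", "PRO", "LEU", "MET",
        ],
    )
)


class Entity(str, Enum):
    """Molecular entity an atom belongs to."""

    AP = "AP"
    RIBOSOME = "RIBOSOME"
    P_TRNA = "P_TRNA"
    E_TRNA = "E_TRNA"
    MRNA = "MRNA"
    OTHER = "OTHER"


#: Entities that count as "the ribosome" for extraction / solvation purposes
#: (everything the nascent chain must lose contact with to be fully out).
RIBOSOME_COMPLEX = (Entity.RIBOSOME, Entity.P_TRNA, Entity.E_TRNA, Entity.MRNA)


@dataclass
class Topology:
    """Structure-of-arrays atom table.

    All arrays share one length (the atom count).  ``entity`` stores
    :class:`Entity` values as strings so the arrays stay plain numpy.
    """

    atom_id: np.ndarray
    atom_name: np.ndarray
    residue_seq: np.ndarray
    residue_name: np.ndarray
    entity: np.ndarray
    is_heavy: np.ndarray
    is_calpha: np.ndarray
    ap_residue_range: Tuple[int, int] = AP_RESIDUE_RANGE

    def __post_init__(self) -> None:
        self.atom_id = np.asarray(self.atom_id, dtype=int)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.residue_seq = np.asarray(self.residue_seq, dtype=int)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.entity = np.asarray(
            [e.value if isinstance(e, Entity) else str(e) for e in self.entity],
            dtype=object,
        )
        self.is_heavy = np.asarray(self.is_heavy, dtype=bool)
        self.is_calpha = np.asarray(self.is_calpha, dtype=bool)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_id)

    def entity_mask(self, *entities: Entity | str) -> np.ndarray:
        wanted = {e.value if isinstance(e, Entity) else str(e) for e in entities}
        return np.isin(self.entity, list(wanted))

    @property
    def ap_mask(self) -> np.ndarray:
        return self.entity_mask(Entity.AP)

    @property
    def ap_residues(self) -> List[int]:
        return sorted(set(self.residue_seq[self.ap_mask].tolist()))

    def ap_residue_atoms(self, residue: int, heavy_only: bool = True) -> np.ndarray:
        """Indices of atoms of one AP residue."""
        mask = self.ap_mask & (self.residue_seq == residue)
        if heavy_only:
            mask &= self.is_heavy
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"AP residue {residue} has no matching atoms")
        return idx

    def validate(self) -> None:
        if len(set(self.atom_id.tolist())) != self.n_atoms:
            raise ValueError("atom_ids are not unique")
        lo, hi = self.ap_residue_range
        present = set(self.residue_seq[self.ap_mask & self.is_heavy].tolist())
        for res in self.ap_residues:
            if lo <= res <= hi and res not in present:
                raise ValueError(f"AP residue {res} has no heavy atom")


@dataclass
class Trajectory:
    """Time-stamped coordinate frames for one replica of one variant.

    coords has shape ``(n_frames, n_atoms, 3)`` in Å; times are in ns.
    """

    topology: Topology
    times: np.ndarray
    coords: np.ndarray
    replica_id: int = 0
    variant: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def validate(self) -> None:
        if self.coords.shape[0] != self.n_frames:
            raise ValueError("frame count does not match number of times")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("coordinate atom count does not match topology")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.n_frames and self.times[0] < 0:
            raise ValueError("times must start at >= 0")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class RegionMap:
    """NT / I / CT partition of the arrest peptide."""

    nt: Tuple[int, int] = (237, 246)
    i: Tuple[int, int] = (247, 253)
    ct: Tuple[int, int] = (254, 260)

    def region_of(self, residue: int) -> str:
        for name, (lo, hi) in (("NT", self.nt), ("I", self.i), ("CT", self.ct)):
            if lo <= residue <= hi:
                return name
        raise ValueError(f"residue {residue} is outside the AP range")

    def residues(self, region: str) -> List[int]:
        lo, hi = {"NT": self.nt, "I": self.i, "CT": self.ct}[region]
        return list(range(lo, hi + 1))

    def validate(self, ap_residue_range: Tuple[int, int] = AP_RESIDUE_RANGE) -> None:
        all_res: List[int] = []
        for region in ("NT", "I", "CT"):
            all_res.extend(self.residues(region))
        if len(all_res) != len(set(all_res)):
            raise ValueError("regions overlap")
        lo, hi = ap_residue_range
        if set(all_res) != set(range(lo, hi + 1)):
            raise ValueError("regions do not cover the AP residue range")


@dataclass
class VariantConfig:
    """Generator parameters for one arrest-peptide variant.

    ``residence_mean`` maps each AP residue to the mean residence time (ns)
    spent at its tunnel site before release; ``math.inf`` means the residue
    never releases (and censors everything C-ward of it).
    ``partial_exit_scale`` scales the covered distance reported for replicas
    that do not fully exit (see the methods note).
    """

    name: str
    residence_mean: Dict[int, float]
    residence_shape: float = 4.0
    extraction_mean: float = math.inf
    extraction_shape: float = 50.0
    exit_probability: float = 0.0
    censor_time: float = 100.0
    n_replicas: int = 20
    f_L: float = 1.0
    partial_exit_scale: float = 1.0

    def validate(self) -> None:
        missing = [r for r in AP_RESIDUES if r not in self.residence_mean]
        if missing:
            raise ValueError(f"residence_mean missing residues {missing}")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")
        if not self.residence_shape > 0:
            raise ValueError("residence_shape must be positive")
        if not 0.0 <= self.exit_probability <= 1.0:
            raise ValueError("exit_probability must be in [0, 1]")


@dataclass
class AnalysisConfig:
    """Distance thresholds and CV geometry used by every analysis."""

    contact_cutoff: float = 3.5          # Å
    ptc_detach_threshold: float = 3.8    # Å
    displacement_threshold: float = 3.5  # Å
    persistence_thresholds: Tuple[float, ...] = (0.50, 0.75)
    cv_target_distance: float = 12.5     # nm

    def validate(self) -> None:
        for name in ("contact_cutoff", "ptc_detach_threshold",
                     "displacement_threshold", "cv_target_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for frac in self.persistence_thresholds:
            if not 0.0 < frac <= 1.0:
                raise ValueError("persistence thresholds must be in (0, 1]")


@dataclass
class EventTable:
    """Per-replica first-passage release times plus the five observables.

    * ``t_release[i]``  – release time of residue *i* (ns) or ``None``
    * ``t_detach_M260`` – metric 1, PTC detach time of the C-terminal residue
    * ``t_release_L259``– release of Leu259 (the translation-resumption proxy)
    * ``extraction_time_T`` – metric 3, full-solvation time minus detach time
    * ``exited``        – metric 4
    * ``covered_distance_D`` – metric 5, nm in CV space
    """

    variant: str
    replica: int
    t_release: Dict[int, Optional[float]]
    t_detach_M260: Optional[float] = None
    t_release_L259: Optional[float] = None
    extraction_time_T: Optional[float] = None
    exited: bool = False
    covered_distance_D: float = 0.0

    @property
    def detached(self) -> bool:
        return self.t_detach_M260 is not None

    @property
    def residues(self) -> List[int]:
        return sorted(self.t_release)

    def n_released(self) -> int:
        return sum(1 for v in self.t_release.values() if v is not None)

    def validate(self, censor_time: Optional[float] = None) -> None:
        times = [self.t_release[r] for r in self.residues]
        seen_censored = False
        prev = -math.inf
        for t in times:
            if t is None:
                seen_censored = True
                continue
            if seen_censored:
                raise ValueError("censoring must propagate C-ward")
            if t < prev:
                raise ValueError("release times must be non-decreasing N->C")
            prev = t
            if censor_time is not None and t > censor_time:
                raise ValueError("release time exceeds the censor bound")
        if self.exited and self.extraction_time_T is None:
            raise ValueError("exited replicas must define an extraction time")
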