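"""Readers and writers for structures, trajectories, configs and event tables.

PDB parsing is delegated to biotite; the XYZ-with-time dialect used for
synthetic trajectories (comment line carrying ``t=<ns>``) and the event-table
CSV are defined here.  Numeric formatting is locale-independent (the decimal
point is fixed by the C locale conventions of ``format``/``float``).
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from .core import (
    AP_RESIDUE_RANGE,
    AnalysisConfig,
    Entity,
    EventTable,
    Topology,
    Trajectory,
    VariantConfig,
)

#: Literal written to CSV for censored times; never a number.
CENSORED = "censored"


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _topology_from_atom_array(atoms, entity_rules: Dict[str, Union[Entity, str]],
                              ap_residue_range=AP_RESIDUE_RANGE) -> Topology:
    entities = []
    for chain in atoms.chain_id:
        if chain not in entity_rules:
            raise ValueError(f"chain {chain!r} has no entity mapping")
        ent = entity_rules[chain]
        entities.append(ent.value if isinstance(ent, Entity) else str(ent))

    element = np.asarray(atoms.element, dtype=object)
    atom_name = np.asarray(atoms.atom_name, dtype=object)
    is_heavy = np.array([str(e).upper() != "H" for e in element], dtype=bool)
    # "CA" with a carbon element distinguishes alpha-carbons from calcium ions
    is_calpha = np.array(
        [n == "CA" and str(e).upper() == "C" for n, e in zip(atom_name, element)],
        dtype=bool,
    )
    topo = Topology(
        atom_id=np.arange(1, len(atom_name) + 1),
        atom_name=atom_name,
        residue_seq=np.asarray(atoms.res_id, dtype=int),
        residue_name=np.asarray(atoms.res_name, dtype=object),
        entity=np.asarray(entities, dtype=object),
        is_heavy=is_heavy,
        is_calpha=is_calpha,
        ap_residue_range=ap_residue_range,
    )
    if not topo.ap_mask.any():
        raise ValueError("no atoms mapped to the AP entity")
    return topo


def read_pdb_topology(path, entity_rules: Dict[str, Union[Entity, str]],
                      ap_residue_range=AP_RESIDUE_RANGE
                      ) -> Tuple[Topology, np.ndarray]:
    """Read a PDB file; return the topology and the first-model coordinates (Å)."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    topo = _topology_from_atom_array(stack[0], entity_rules, ap_residue_range)
    return topo, np.asarray(stack.coord[0], dtype=float)


def read_pdb_trajectory(path, entity_rules: Dict[str, Union[Entity, str]],
                        dt: float, ap_residue_range=AP_RESIDUE_RANGE,
                        replica_id: int = 0, variant: str = "") -> Trajectory:
    """Read a multi-model PDB as a trajectory with uniform frame spacing ``dt`` ns."""
    from biotite.structure.io.pdb import PDBFile

    if dt <= 0:
        raise ValueError("dt must be positive")
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    topo = _topology_from_atom_array(stack[0], entity_rules, ap_residue_range)
    coords = np.asarray(stack.coord, dtype=float)
    times = np.arange(coords.shape[0]) * dt
    traj = Trajectory(topo, times, coords, replica_id=replica_id, variant=variant)
    traj.validate()
    return traj


# ---------------------------------------------------------------------------
# XYZ with time comments
# ---------------------------------------------------------------------------

def write_xyz_trajectory(traj: Trajectory, path) -> None:
    """Write frames in XYZ format; the comment line carries ``t=<ns>``."""
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"{traj.topology.n_atoms}\n")
            fh.write(f"t={traj.times[k]:.6f} ns\n")
            for name, xyz in zip(traj.topology.atom_name, traj.coords[k]):
                fh.write(f"{name} {xyz[0]:.3f} {xyz[1]:.3f} {xyz[2]:.3f}\n")


def read_xyz_trajectory(path, topology: Topology, dt: Optional[float] = None,
                        replica_id: int = 0, variant: str = "") -> Trajectory:
    """Read the XYZ dialect back onto an existing topology.

    Frame times come from the ``t=<ns>`` comments when present, otherwise
    from ``k * dt``.
    """
    n_expected = topology.n_atoms
    times: List[float] = []
    frames: List[np.ndarray] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_idx = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].strip())
        except ValueError as exc:
            raise ValueError(f"frame {frame_idx}: bad atom-count line") from exc
        if count != n_expected:
            raise ValueError(
                f"frame {frame_idx}: atom count {count} != topology ({n_expected})"
            )
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        t: Optional[float] = None
        for token in comment.split():
            if token.startswith("t="):
                t = float(token[2:])
        atom_lines = lines[pos + 2: pos + 2 + count]
        if len(atom_lines) < count:
            raise ValueError(f"frame {frame_idx}: truncated frame")
        coords = np.empty((count, 3), dtype=float)
        for i, line in enumerate(atom_lines):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"frame {frame_idx}: truncated atom line {i}")
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        if t is None:
            if dt is None:
                raise ValueError("no t= comment and no dt supplied")
            t = frame_idx * dt
        times.append(t)
        frames.append(coords)
        pos += 2 + count
        frame_idx += 1
    traj = Trajectory(topology, np.array(times), np.array(frames),
                      replica_id=replica_id, variant=variant)
    traj.validate()
    return traj


# ---------------------------------------------------------------------------
# Event-table CSV
# ---------------------------------------------------------------------------

EVENT_HEADER = ["variant", "replica", "residue", "t_release_ns", "censored",
                "extraction_ns", "exited", "covered_nm"]


def _fmt_time(value: Optional[float]) -> str:
    return CENSORED if value is None else f"{value:.9g}"


def write_event_tables(tables: Union[EventTable, Sequence[EventTable]], path) -> None:
    """Write one row per (replica, residue); censored times as a literal string."""
    if isinstance(tables, EventTable):
        tables = [tables]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_HEADER)
        for table in tables:
            for residue in table.residues:
                t = table.t_release[residue]
                writer.writerow([
                    table.variant,
                    table.replica,
                    residue,
                    _fmt_time(t),
                    "1" if t is None else "0",
                    _fmt_time(table.extraction_time_T),
                    "1" if table.exited else "0",
                    f"{table.covered_distance_D:.9g}",
                ])


# spec-facing singular aliases
def write_event_table(table, path) -> None:
    write_event_tables(table, path)


def read_event_tables(path) -> List[EventTable]:
    """Read the event CSV back; duplicate (replica, residue) rows are an error."""
    rows_by_replica: Dict[Tuple[str, int], Dict[int, Optional[float]]] = {}
    meta: Dict[Tuple[str, int], Tuple[Optional[float], bool, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            key = (row["variant"], int(row["replica"]))
            residue = int(row["residue"])
            releases = rows_by_replica.setdefault(key, {})
            if residue in releases:
                raise ValueError(
                    f"duplicate row for replica {key[1]}, residue {residue}"
                )
            raw = row["t_release_ns"]
            releases[residue] = None if raw == CENSORED else float(raw)
            extraction = row.get("extraction_ns", CENSORED)
            meta[key] = (
                None if extraction in (CENSORED, "", None) else float(extraction),
                row.get("exited", "0") == "1",
                float(row.get("covered_nm", 0.0) or 0.0),
            )
    tables = []
    for (variant, replica), releases in rows_by_replica.items():
        extraction, exited, covered = meta[(variant, replica)]
        residues = sorted(releases)
        table = EventTable(
            variant=variant,
            replica=replica,
            t_release=releases,
            t_detach_M260=releases.get(max(residues)),
            t_release_L259=releases.get(259),
            extraction_time_T=extraction,
            exited=exited,
            covered_distance_D=covered,
        )
        table.validate()
        tables.append(table)
    return tables


def read_event_table(path) -> List[EventTable]:
    return read_event_tables(path)


# ---------------------------------------------------------------------------
# YAML configs
# ---------------------------------------------------------------------------

def _config_to_dict(config: VariantConfig) -> dict:
    return {
        "name": config.name,
        "residence_mean": {
            int(r): ("inf" if math.isinf(v) else float(v))
            for r, v in sorted(config.residence_mean.items())
        },
        "residence_shape": config.residence_shape,
        "extraction_mean": ("inf" if math.isinf(config.extraction_mean)
                            else float(config.extraction_mean)),
        "extraction_shape": config.extraction_shape,
        "exit_probability": config.exit_probability,
        "censor_time": config.censor_time,
        "n_replicas": config.n_replicas,
        "f_L": config.f_L,
        "partial_exit_scale": config.partial_exit_scale,
    }


def _config_from_dict(data: dict) -> VariantConfig:
    def as_float(v):
        return math.inf if v in ("inf", ".inf") else float(v)

    config = VariantConfig(
        name=str(data["name"]),
        residence_mean={int(r): as_float(v)
                        for r, v in data["residence_mean"].items()},
        residence_shape=float(data.get("residence_shape", 4.0)),
        extraction_mean=as_float(data.get("extraction_mean", "inf")),
        extraction_shape=float(data.get("extraction_shape", 50.0)),
        exit_probability=float(data.get("exit_probability", 0.0)),
        censor_time=float(data.get("censor_time", 100.0)),
        n_replicas=int(data.get("n_replicas", 20)),
        f_L=float(data.get("f_L", 1.0)),
        partial_exit_scale=float(data.get("partial_exit_scale", 1.0)),
    )
    config.validate()
    return config


def write_variant_configs(configs: Dict[str, VariantConfig], path) -> None:
    payload = {"variants": [_config_to_dict(c) for c in configs.values()]}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_variant_configs(path) -> Dict[str, VariantConfig]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    configs = {}
    for entry in payload["variants"]:
        config = _config_from_dict(entry)
        configs[config.name] = config
    return configs


def write_analysis_config(config: AnalysisConfig, path) -> None:
    data = {
        "contact_cutoff": config.contact_cutoff,
        "ptc_detach_threshold": config.ptc_detach_threshold,
        "displacement_threshold": config.displacement_threshold,
        "persistence_thresholds": list(config.persistence_thresholds),
        "cv_target_distance": config.cv_target_distance,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_analysis_config(path) -> AnalysisConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    config = AnalysisConfig(
        contact_cutoff=float(data.get("contact_cutoff", 3.5)),
        ptc_detach_threshold=float(data.get("ptc_detach_threshold", 3.8)),
        displacement_threshold=float(data.get("displacement_threshold", 3.5)),
        persistence_thresholds=tuple(data.get("persistence_thresholds", (0.5, 0.75))),
        cv_target_distance=float(data.get("cv_target_distance", 12.5)),
    )
    config.validate()
    return config
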