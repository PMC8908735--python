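"""End-to-end orchestration: simulate -> analyze -> rank, with manifests.

Replica studies live or die by seed bookkeeping, so every run writes a
manifest with the master seed, the per-replica child seeds, the configs and
a checksum inventory of every output file; re-running with the same master
seed reproduces the event CSVs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import AnalysisConfig, EventTable, VariantConfig
from .io import write_event_tables
from .kinetics import VariantKinetics, ensemble_profile, rank_variants
from .synth import child_seeds, default_variant_configs, sample_ensemble


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fmt(value: Optional[float], censored_label: str, digits: int = 1) -> str:
    if value is None:
        return censored_label
    return f"{value:.{digits}f}"


def summary_table(kinetics: Sequence[VariantKinetics]) -> pd.DataFrame:
    """Observables per variant, one row each: detach time, extraction time,
    detach/exit counts, covered distance and the experimental f_L."""
    rows = []
    for vk in kinetics:
        m, se = vk.t_M260
        mT, seT = vk.T_extraction
        mD, seD = vk.D_mean
        rows.append({
            "variant": vk.variant,
            "detach_time_ns": "no detach" if m is None
            else f"{m:.1f} ± {se:.1f}",
            "extraction_time_ns": "no extraction" if mT is None
            else f"{mT:.1f} ± {seT:.1f}",
            "n_detached": f"{vk.n_detached}/{vk.n_replicas}",
            "n_exited": f"{vk.n_exited}/{vk.n_replicas}",
            "covered_distance_nm": f"{mD:.2f} ± {seD:.2f}",
            "f_L": vk.f_L,
        })
    return pd.DataFrame(rows)


def run_pipeline(out_dir, master_seed: int,
                 configs: Optional[Dict[str, VariantConfig]] = None,
                 n_replicas: Optional[int] = None,
                 analysis: Optional[AnalysisConfig] = None) -> Path:
    """Simulate replica ensembles for every variant, compute kinetics,
    rank, and write all artifacts plus the manifest.  Returns the run dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    configs = configs or default_variant_configs()
    analysis = analysis or AnalysisConfig()
    analysis.validate()

    manifest: dict = {
        "package_version": __version__,
        "master_seed": int(master_seed),
        "variants": list(configs),
        "analysis_config": dataclasses.asdict(analysis),
        "n_replicas": {},
        "child_seeds": {},
        "files": {},
    }

    all_kinetics: List[VariantKinetics] = []
    for name, config in configs.items():
        n = n_replicas or config.n_replicas
        tables = sample_ensemble(config, master_seed, n_replicas=n,
                                 cv_target_nm=analysis.cv_target_distance)
        safe = name.replace("/", "_")
        events_path = out / f"events_{safe}.csv"
        write_event_tables(tables, events_path)
        vk = ensemble_profile(tables, f_L=config.f_L)
        (out / f"kinetics_{safe}.json").write_text(
            json.dumps(vk.to_dict(), indent=1))
        all_kinetics.append(vk)
        manifest["n_replicas"][name] = n
        manifest["child_seeds"][name] = child_seeds(master_seed, n)

    summary = summary_table(all_kinetics)
    summary.to_csv(out / "summary.csv", index=False)

    ranking = rank_variants(all_kinetics)
    (out / "ranking.json").write_text(json.dumps({
        "order_strongest_first": ranking.order,
        "ties": [list(t) for t in ranking.ties],
        "spearman_vs_1_minus_fL": ranking.spearman,
    }, indent=1))

    for path in sorted(out.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][path.name] = _checksum(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def make_report(run_dir, plots: bool = False) -> Path:
    """Assemble a deterministic human-readable report from a completed run.

    Regeneration is idempotent; missing inputs raise a named error.
    """
    run = Path(run_dir)
    summary_path = run / "summary.csv"
    ranking_path = run / "ranking.json"
    for needed in (summary_path, ranking_path):
        if not needed.exists():
            raise FileNotFoundError(f"missing pipeline artifact: {needed}")
    summary = pd.read_csv(summary_path)
    ranking = json.loads(ranking_path.read_text())

    lines = ["# Arrest-peptide extraction report", ""]
    lines.append("## Replica observables (per variant)")
    lines.append("")
    lines.append(summary.to_string(index=False))
    lines.append("")
    lines.append("## Stalling-strength ranking (strongest first)")
    lines.append("")
    for i, name in enumerate(ranking["order_strongest_first"], 1):
        lines.append(f"{i}. {name}")
    if ranking.get("ties"):
        ties = ", ".join(" ≈ ".join(pair) for pair in ranking["ties"])
        lines.append(f"\nTies (within one combined SE): {ties}")
    rho = ranking.get("spearman_vs_1_minus_fL")
    if rho is not None:
        lines.append(f"\nSpearman concordance with (1 − f_L): {rho:.3f}")
    lines.append("")

    lines.append("## Per-residue kinetic profiles")
    lines.append("")
    profile_files = sorted(run.glob("kinetics_*.json"))
    if not profile_files:
        raise FileNotFoundError("no kinetics_*.json profiles in run directory")
    for path in profile_files:
        data = json.loads(path.read_text())
        lines.append(f"### {data['variant']}")
        lines.append("residue  mean_t_ns  se_t_ns  mean_dt_ns  n")
        for res in sorted(data["t_profile"], key=int):
            mean, se, n = data["t_profile"][res]
            dmean = data["dt_profile"][res][0]
            lines.append(
                f"{res:>7}  {_fmt(mean, 'censored', 2):>9}  "
                f"{_fmt(se, '-', 2):>7}  {_fmt(dmean, 'censored', 2):>10}  {n}")
        lines.append("")

    if plots:
        _write_plots(run, profile_files)

    report_path = run / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path


def _write_plots(run: Path, profile_files: Sequence[Path]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_t, ax_dt) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    for path in profile_files:
        data = json.loads(path.read_text())
        residues = sorted(data["t_profile"], key=int)
        means = [data["t_profile"][r][0] for r in residues]
        dts = [data["dt_profile"][r][0] for r in residues]
        xs = [int(r) for r in residues]
        ax_t.plot(xs, [m if m is not None else math.nan for m in means],
                  marker="o", label=data["variant"])
        ax_dt.plot(xs, [d if d is not None else math.nan for d in dts],
                   marker="o", label=data["variant"])
    ax_t.set_ylabel("⟨t⟩ (ns)")
    ax_dt.set_ylabel("⟨Δt⟩ (ns)")
    ax_dt.set_xlabel("AP residue")
    ax_t.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(run / "profiles.png", dpi=120)
    plt.close(fig)
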