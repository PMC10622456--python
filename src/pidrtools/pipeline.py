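"""Configuration-driven end-to-end analysis.

``run_analysis`` executes the full flow on one system: load -> leaflet
assignment -> equilibration masking -> bilayer metrics -> interaction time
series and enrichment -> reaction coordinates -> reaction-coordinate and
dihedral-window selection -> 2D density -> substate clusters -> per-cluster
conditioning (z-profiles, hydrogen-bond frequency maps) -> report.  All
results are written as tidy CSV/JSON artifacts plus a plain-text density
matrix; the report carries a provenance hash of the configuration and
inputs.  The whole pipeline is deterministic given its configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import bilayer as B
from . import ensemble as E
from . import interactions as I
from .membrane import PidrError, Trajectory, assign_leaflets, read_structure
from .groups import assign_groups

log = logging.getLogger("pidrtools.pipeline")

#: Equilibration windows (ns) excluded before computing equilibrium
#: properties, per system.
DEFAULT_EQUILIBRATION_NS: Dict[str, float] = {
    "Rheb": 500.0,
    "RhoA": 500.0,
    "Rap1A": 1000.0,
    "Rap1B": 1000.0,
    "Cdc42b": 1000.0,
    "Rac1": 2200.0,
}


@dataclass
class AnalysisConfig:
    """Validated configuration for :func:`run_analysis`.

    Defaults are the study values: hydrogen bonds at 3.1 A / 30 deg,
    contacts at 4.0 A, a 100 x 72 density grid (5 degree Phi bins), a 25%
    peak threshold.
    """

    input: Optional[str] = None  # structure path; may be omitted when a
    # Trajectory object is passed to run_analysis directly
    dialect: str = "pdb"
    system: Optional[str] = None  # name used to look up t_eq defaults
    t_eq_ns: Optional[float] = None
    frame_interval_ns: float = 0.1
    hb_distance_cutoff: float = 3.1
    hb_angle_cutoff: float = 30.0
    contact_cutoff: float = 4.0
    grid: Tuple[int, int] = (100, 72)
    bandwidth: Optional[Tuple[float, float]] = None
    peak_threshold: float = 0.25
    min_occupancy: float = 0.05
    phi_window: Optional[int] = None  # None -> choose automatically
    rc: Optional[str] = None  # 'Rg' / 'RMSD' or None -> choose automatically
    exclude_peptides: List[int] = field(default_factory=list)  # molecule ids
    outdir: str = "pidrtools_out"
    seed: int = 0  # forwarded to `synth`; analysis itself is deterministic

    def __post_init__(self) -> None:
        if self.hb_distance_cutoff <= 0 or not 0 < self.hb_angle_cutoff < 90:
            raise PidrError("invalid hydrogen-bond criterion in config")
        if self.contact_cutoff <= 0:
            raise PidrError("contact cutoff must be positive")
        if self.rc not in (None, "Rg", "RMSD"):
            raise PidrError("rc must be 'Rg', 'RMSD' or omitted")
        self.grid = tuple(self.grid)  # type: ignore[assignment]

    @property
    def t_eq(self) -> float:
        if self.t_eq_ns is not None:
            return float(self.t_eq_ns)
        if self.system in DEFAULT_EQUILIBRATION_NS:
            return DEFAULT_EQUILIBRATION_NS[self.system]
        return 0.0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PidrError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = list(self.grid)
        return d


@dataclass
class Report:
    """Summary of one pipeline run; every number traces to a CSV/JSON
    artifact in the output directory."""

    config: dict
    provenance: str
    n_frames_analyzed: int
    n_conformers: int
    leaflet_counts: Dict[str, int]
    bilayer: Dict[str, float]
    interactions: Dict[str, object]
    rc_name: str
    phi_window: int
    clusters: List[dict]
    oxygen_preference: Dict[str, Tuple[int, int]]
    artifacts: List[str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _provenance(config: AnalysisConfig) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(config.to_dict(), sort_keys=True).encode())
    if config.input and Path(config.input).exists():
        h.update(Path(config.input).read_bytes())
    return h.hexdigest()[:16]


def run_analysis(
    config: AnalysisConfig, trajectory: Optional[Trajectory] = None
) -> Report:
    """Run the full analysis flow and write artifacts to ``config.outdir``.

    ``trajectory`` may be supplied directly (e.g. from the synthetic
    generator); otherwise ``config.input`` is read.  Peptides listed in
    ``config.exclude_peptides`` (molecule ids) are dropped from peptide
    analyses, mirroring exclusion of peptides whose anchor never inserted.
    """
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: List[str] = []

    def stage(name: str):
        log.info("stage %-22s t=%.1fs", name, time.time() - t_start)

    stage("load")
    if trajectory is None:
        if not config.input:
            raise PidrError("config.input is required when no trajectory is given")
        trajectory = read_structure(
            config.input, config.dialect, frame_interval=config.frame_interval_ns
        )
        assign_groups(trajectory.topology)
    top = trajectory.topology

    stage("leaflets")
    leaflets = assign_leaflets(trajectory.frame(0), top)
    counts = leaflets.counts(top)
    n_pc = counts.get("mixed_POPC", 0)
    n_ps = counts.get("mixed_POPS", 0)

    stage("equilibration mask")
    mask = E.equilibration_mask(trajectory, config.t_eq)
    if not mask.any():
        raise PidrError(
            f"equilibration time {config.t_eq} ns leaves no frames to analyse"
        )

    peptides = [p for p in top.peptide_ids if p not in config.exclude_peptides]
    if not peptides:
        raise PidrError("all peptides excluded; nothing to analyse")

    stage("bilayer metrics")
    bts = B.bilayer_timeseries(trajectory, leaflets, frame_mask=mask)
    f = outdir / "bilayer_timeseries.csv"
    bts.to_csv(f, index=False)
    artifacts.append(f.name)
    bilayer_summary = {
        "APL_mean": float(bts["APL"].mean()),
        "APL_sd": float(bts["APL"].std(ddof=1)) if len(bts) > 1 else 0.0,
        "PP_mean": float(bts["PP"].mean()),
        "PP_sd": float(bts["PP"].std(ddof=1)) if len(bts) > 1 else 0.0,
    }
    for pid in peptides:
        col = f"I_peptide{pid}"
        if col in bts:
            bilayer_summary[f"{col}_mean"] = float(bts[col].mean())

    stage("interactions")
    criterion = I.HBCriterion(config.hb_distance_cutoff, config.hb_angle_cutoff)
    records = I.interaction_timeseries(
        trajectory,
        criterion=criterion,
        contact_cutoff=config.contact_cutoff,
        frame_mask=mask,
        peptide_ids=peptides,
    )
    idf = I.records_to_frame(records)
    f = outdir / "interaction_timeseries.csv"
    idf.to_csv(f, index=False)
    artifacts.append(f.name)
    interaction_summary = I.summarize_interactions(records, n_pc=n_pc, n_ps=n_ps)

    stage("reaction coordinates")
    # restrict to included peptides by masking the pooled series afterwards
    if config.phi_window is None:
        phi_window, _info = E.choose_phi_quad(trajectory, frame_mask=mask)
    else:
        phi_window = config.phi_window
    desc = E.compute_descriptors(trajectory, frame_mask=mask, phi_window=phi_window)
    keep = np.isin(desc.peptide_id, peptides)
    desc = E.DescriptorSeries(
        frame_index=desc.frame_index[keep],
        peptide_id=desc.peptide_id[keep],
        rg=desc.rg[keep],
        rmsd=desc.rmsd[keep],
        phi=desc.phi[keep],
        orientation=desc.orientation[keep],
        phi_window=phi_window,
    )
    ddf = pd.DataFrame(
        {
            "frame": desc.frame_index,
            "peptide": desc.peptide_id,
            "Rg": desc.rg,
            "RMSD": desc.rmsd,
            "Phi": desc.phi,
            "orientation": desc.orientation,
        }
    )
    f = outdir / "reaction_coordinates.csv"
    ddf.to_csv(f, index=False)
    artifacts.append(f.name)

    stage("rc selection")
    rc_name = config.rc or E.choose_global_rc(desc)
    rc_values = desc.rg if rc_name == "Rg" else desc.rmsd

    stage("density")
    dens = E.density2d(
        rc_values,
        desc.phi,
        grid=config.grid,
        bandwidth=config.bandwidth,
        rc_name=rc_name,
    )
    f = outdir / "density_matrix.txt"
    header = (
        f"P({rc_name}, Phi) density; rows = {rc_name} bins "
        f"[{dens.rc_edges[0]:.4f}, {dens.rc_edges[-1]:.4f}], "
        f"cols = Phi bins [-180, 180]"
    )
    np.savetxt(f, dens.values, header=header)
    artifacts.append(f.name)

    stage("clusters")
    clusters = E.find_clusters(
        dens,
        rc_values,
        desc.phi,
        min_occupancy=config.min_occupancy,
        peak_threshold=config.peak_threshold,
    )
    cluster_rows = []
    for c in clusters:
        cluster_rows.append(
            {
                "label": c.label,
                f"center_{rc_name}": c.center_rc,
                "center_Phi": c.center_phi,
                f"sigma_{rc_name}": c.sigma_rc,
                "sigma_Phi": c.sigma_phi,
                "occupancy": c.occupancy,
                "basin_weight": c.basin_weight,
                "n_members": c.n_members,
            }
        )

    stage("per-cluster conditioning")
    for c in clusters:
        members = desc.members(c.member_mask)
        prof = B.sidechain_z_profile(trajectory, members, leaflets)
        f = outdir / f"cluster{c.label}_zprofile.csv"
        prof.to_frame().to_csv(f, index=False)
        artifacts.append(f.name)
        freq = I.residue_hb_frequency_map(records, members=members)
        f = outdir / f"cluster{c.label}_hb_frequency.csv"
        pd.DataFrame(
            {"residue": list(freq), "hb_frequency": list(freq.values())}
        ).to_csv(f, index=False)
        artifacts.append(f.name)

    stage("oxygen preference")
    oxy = I.oxygen_site_preference(trajectory, criterion=criterion, frame_mask=mask)
    f = outdir / "oxygen_site_preference.json"
    f.write_text(json.dumps({k: list(v) for k, v in oxy.items()}, indent=1))
    artifacts.append(f.name)

    report = Report(
        config=config.to_dict(),
        provenance=_provenance(config),
        n_frames_analyzed=int(mask.sum()),
        n_conformers=desc.n,
        leaflet_counts=counts,
        bilayer=bilayer_summary,
        interactions=interaction_summary,
        rc_name=rc_name,
        phi_window=phi_window,
        clusters=cluster_rows,
        oxygen_preference=oxy,
        artifacts=artifacts,
    )
    f = outdir / "report.json"
    f.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))
    stage("done")
    return report


def run_descriptors(fasta_path, window: int = 19) -> pd.DataFrame:
    """Descriptor table for a FASTA file (see
    :func:`pidrtools.descriptors.scan_fasta`)."""
    from .descriptors import scan_fasta

    return scan_fasta(fasta_path, window=window)
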