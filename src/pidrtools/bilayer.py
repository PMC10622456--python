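"""Bilayer structural observables and peptide depth profiles.

Area per lipid (APL) is the lateral box area divided by the lipid count of
the pure-POPC leaflet; bilayer thickness (P-P) is the z-distance between
the mean phosphorus positions of the two leaflets; the prenyl insertion
depth I is the z-distance of the prenyl-chain centre of mass from the
bilayer (all-lipid) centre of mass.  Sidechain z-profiles report, per
residue, the mean +/- SD of the sidechain centre-of-mass z relative to the
mean phosphate plane of the peptide-hosting (mixed) leaflet; positive is
toward water.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .membrane import (
    Frame,
    GroupError,
    LeafletAssignment,
    PidrError,
    Topology,
    Trajectory,
    center_of_mass,
)


def area_per_lipid(frame: Frame, leaflets: LeafletAssignment) -> float:
    """Lateral box area divided by the pure-leaflet lipid count (Angstrom^2)."""
    n_pure = len(leaflets.lipids("pure"))
    if n_pure == 0:
        raise PidrError("pure leaflet is empty; APL undefined")
    return float(frame.box[0] * frame.box[1] / n_pure)


def bilayer_thickness(frame: Frame, topology: Topology) -> float:
    """Mean z of upper-leaflet P atoms minus mean z of lower-leaflet P atoms."""
    p = topology.group("lipid_P")
    if p.size < 2:
        raise PidrError("need phosphorus atoms in both leaflets")
    z = frame.coordinates[p, 2]
    lipid_atoms = np.nonzero(topology.kinds == "lipid")[0]
    z_mid = float(
        np.average(
            frame.coordinates[lipid_atoms, 2], weights=topology.masses[lipid_atoms]
        )
    )
    upper = z[z > z_mid]
    lower = z[z <= z_mid]
    if upper.size == 0 or lower.size == 0:
        raise PidrError("one leaflet has no phosphorus atoms")
    return float(upper.mean() - lower.mean())


def insertion_depth(
    frame: Frame, prenyl_group: np.ndarray, topology: Topology
) -> float:
    """|z_COM(prenyl chain) - z_COM(all lipid atoms)|, mass-weighted."""
    prenyl = np.asarray(prenyl_group, dtype=int)
    if prenyl.size == 0:
        raise GroupError("empty prenyl group")
    lipid_atoms = np.nonzero(topology.kinds == "lipid")[0]
    z_pre = center_of_mass(frame.coordinates, prenyl, topology.masses)[2]
    z_bil = center_of_mass(frame.coordinates, lipid_atoms, topology.masses)[2]
    return float(abs(z_pre - z_bil))


@dataclass
class ZProfile:
    """Per-residue sidechain depth statistics relative to the mixed-leaflet
    phosphate plane (positive toward water)."""

    residues: List[int]
    residue_names: List[str]
    mean: np.ndarray
    sd: np.ndarray
    phosphate_offset: float  # 0 by construction of the reference plane
    ester_offset: float  # mean z of mixed-leaflet ester oxygens - plane

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residues,
                "residue_name": self.residue_names,
                "z_mean": self.mean,
                "z_sd": self.sd,
            }
        )


def _mixed_leaflet_p(topology: Topology, leaflets: LeafletAssignment) -> np.ndarray:
    p = topology.group("lipid_P")
    mixed = set(leaflets.lipids("mixed"))
    return p[np.isin(topology.molecule_ids[p], list(mixed))]


def sidechain_z_profile(
    trajectory: Trajectory,
    members: Sequence[Tuple[int, int]],
    leaflets: LeafletAssignment,
) -> ZProfile:
    """Sidechain z-profile over a set of (frame, peptide) conformers.

    The reference plane is the mean phosphate z of the mixed leaflet in each
    frame, kept fixed to that leaflet (the peptides never translocate).  A
    glycine entry falls back to its backbone C-alpha.  The sign convention
    is +z toward water for the upper leaflet and mirrored for the lower, so
    "inserted" is always negative.
    """
    top = trajectory.topology
    members = list(members)
    if not members:
        raise PidrError("empty conformer set for z-profile")
    pids = sorted({p for _f, p in members})
    for pid in pids:
        if pid not in top.peptide_ids:
            raise PidrError(f"unknown peptide id {pid}")
    p_mixed = _mixed_leaflet_p(top, leaflets)
    if p_mixed.size == 0:
        raise PidrError("mixed leaflet has no phosphorus atoms")
    sign = 1.0 if leaflets.upper_is_mixed else -1.0

    # residue axis from the first peptide (all peptides share the sequence)
    pid0 = pids[0]
    pep_atoms = np.nonzero(
        (top.kinds == "peptide") & (top.molecule_ids == pid0)
    )[0]
    residues = sorted(set(top.residue_indices[pep_atoms].tolist()))
    resnames = [
        str(top.residue_names[pep_atoms[top.residue_indices[pep_atoms] == r][0]])
        for r in residues
    ]

    values: Dict[int, List[float]] = {r: [] for r in residues}
    ester_vals: List[float] = []
    ester = top.group("ester_oxygens")
    mixed = set(leaflets.lipids("mixed"))
    ester_mixed = ester[np.isin(top.molecule_ids[ester], list(mixed))]
    for fi, pid in members:
        coords = trajectory.coordinates[fi]
        plane = float(coords[p_mixed, 2].mean())
        if ester_mixed.size:
            ester_vals.append(sign * (float(coords[ester_mixed, 2].mean()) - plane))
        for r in residues:
            side = top.group(f"peptide{pid}_sidechain_r{r}")
            if side.size == 0:  # glycine: backbone placeholder
                side = top.group(f"peptide{pid}_ca")
                ridx = side[top.residue_indices[side] == r]
                side = ridx
            com = center_of_mass(coords, side, top.masses)
            values[r].append(sign * (com[2] - plane))

    mean = np.array([np.mean(values[r]) for r in residues])
    # population SD: the profile summarises the sampled ensemble itself
    sd = np.array([np.std(values[r]) for r in residues])
    return ZProfile(
        residues=residues,
        residue_names=resnames,
        mean=mean,
        sd=sd,
        phosphate_offset=0.0,
        ester_offset=float(np.mean(ester_vals)) if ester_vals else np.nan,
    )


def bilayer_timeseries(
    trajectory: Trajectory,
    leaflets: LeafletAssignment,
    frame_mask: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Tidy per-frame table: time, APL, P-P, and per-peptide insertion depth."""
    top = trajectory.topology
    if frame_mask is None:
        frame_mask = np.ones(trajectory.n_frames, dtype=bool)
    fidx = np.nonzero(frame_mask)[0]
    rows = []
    prenyl = {
        pid: top.group(f"peptide{pid}_prenyl_carbons") for pid in top.peptide_ids
    }
    for fi in fidx:
        frame = trajectory.frame(int(fi))
        row = {
            "frame": int(fi),
            "time_ns": frame.time,
            "APL": area_per_lipid(frame, leaflets),
            "PP": bilayer_thickness(frame, top),
        }
        for pid, grp in prenyl.items():
            if grp.size:
                row[f"I_peptide{pid}"] = insertion_depth(frame, grp, top)
        rows.append(row)
    return pd.DataFrame(rows)
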