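"""Hydrogen-bond and van der Waals contact statistics with lipids.

Hydrogen bonds between peptide sidechain donors and lipid headgroup oxygen
acceptors use a donor-acceptor distance cutoff (default 3.1 Angstrom) and a
30 degree cutoff on the angle at the donor between the D->H and D->A
vectors (i.e. deviation from linearity).  vdW contacts count peptide
carbon / lipid acyl-chain carbon pairs within 4.0 Angstrom.  Distances use
the minimal-image convention laterally (x, y) only.

Counts are reported per peptide and split by lipid species; the
composition-normalised PS enrichment fold is
``(mean_PS / mean_PC) * (n_PC / n_PS)``, >1 indicating sorting of the
anionic PS lipids toward the peptide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .groups import BASIC_RESIDUES, one_letter
from .membrane import (
    Frame,
    GroupError,
    PidrError,
    Topology,
    Trajectory,
    minimum_image_xy,
)

SPECIES = ("POPC", "POPS")


@dataclass(frozen=True)
class HBCriterion:
    """Geometric hydrogen-bond definition."""

    d_cut: float = 3.1  # donor-acceptor distance cutoff, Angstrom
    theta_cut: float = 30.0  # D->H vs D->A angle cutoff, degrees

    def __post_init__(self) -> None:
        if self.d_cut <= 0:
            raise ValueError("d_cut must be positive")
        if not 0 < self.theta_cut < 90:
            raise ValueError("theta_cut must be in (0, 90) degrees")


DEFAULT_HB = HBCriterion()
DEFAULT_CONTACT_CUTOFF = 4.0


def detect_hydrogen_bonds(
    frame: Frame,
    donors: np.ndarray,
    acceptors: np.ndarray,
    topology: Topology,
    criterion: HBCriterion = DEFAULT_HB,
) -> List[Tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) triples satisfying the criterion.

    A triple qualifies iff dist(D, A) <= d_cut and the angle at the donor
    between D->H and D->A is <= theta_cut.  Each (D, A) pair is reported at
    most once per hydrogen.  Donors must carry bonded hydrogens in
    ``topology.donor_hydrogens``.
    """
    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if donors.size == 0 or acceptors.size == 0:
        return []
    for d in donors:
        if int(d) not in topology.donor_hydrogens:
            raise GroupError(f"donor atom {int(d)} has no bonded hydrogen")
    coords = frame.coordinates
    box = frame.box
    delta = minimum_image_xy(
        coords[acceptors][None, :, :] - coords[donors][:, None, :], box
    )
    dist = np.linalg.norm(delta, axis=2)
    cand = np.nonzero(dist <= criterion.d_cut)
    cos_cut = math.cos(math.radians(criterion.theta_cut))
    out: List[Tuple[int, int, int]] = []
    for di, ai in zip(*cand):
        d = int(donors[di])
        a = int(acceptors[ai])
        da = delta[di, ai]
        nda = np.linalg.norm(da)
        if nda == 0:
            continue
        for h in topology.donor_hydrogens[d]:
            dh = minimum_image_xy(coords[h] - coords[d], box)
            ndh = np.linalg.norm(dh)
            if ndh == 0:
                continue
            cosang = float(np.dot(dh, da) / (ndh * nda))
            if cosang >= cos_cut - 1e-12:
                out.append((d, h, a))
    out.sort()
    return out


def count_vdw_contacts(
    frame: Frame,
    peptide_carbons: np.ndarray,
    lipid_acyl_carbons: np.ndarray,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> int:
    """Number of carbon-carbon pairs within ``cutoff`` (minimal image in x,y)."""
    pc = np.asarray(peptide_carbons, dtype=int)
    lc = np.asarray(lipid_acyl_carbons, dtype=int)
    if pc.size == 0 or lc.size == 0:
        return 0
    delta = minimum_image_xy(
        frame.coordinates[lc][None, :, :] - frame.coordinates[pc][:, None, :],
        frame.box,
    )
    dist2 = np.einsum("ijk,ijk->ij", delta, delta)
    return int(np.count_nonzero(dist2 <= cutoff * cutoff))


@dataclass
class InteractionRecord:
    """Per-frame, per-peptide interaction counts."""

    frame_index: int
    peptide_id: int
    n_hb: Dict[str, int]  # species -> count
    n_c: Dict[str, int]  # species -> count
    n_c_lipidated: Dict[str, int]  # species -> count via prenyl/palmitoyl carbons
    hb_residues_ps: Tuple[int, ...]  # residue indices with >=1 HB to POPS oxygens
    hb_acceptor_class_ps: Dict[str, int]  # 'carboxyl'/'phosphate' -> count

    @property
    def n_hb_total(self) -> int:
        return sum(self.n_hb.values())

    @property
    def n_c_total(self) -> int:
        return sum(self.n_c.values())

    def n_c_nonlipidated(self, species: str) -> int:
        return self.n_c[species] - self.n_c_lipidated[species]


def interaction_timeseries(
    trajectory: Trajectory,
    criterion: HBCriterion = DEFAULT_HB,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    frame_mask: Optional[np.ndarray] = None,
    peptide_ids: Optional[Sequence[int]] = None,
) -> List[InteractionRecord]:
    """One :class:`InteractionRecord` per peptide per masked frame."""
    top = trajectory.topology
    if frame_mask is None:
        frame_mask = np.ones(trajectory.n_frames, dtype=bool)
    fidx = np.nonzero(frame_mask)[0]
    if fidx.size == 0:
        raise PidrError("empty frame mask")
    pids = list(peptide_ids) if peptide_ids is not None else top.peptide_ids

    acc = {sp: top.group(f"headgroup_oxygens_{sp}") for sp in SPECIES}
    acyl = {sp: top.group(f"acyl_carbons_{sp}") for sp in SPECIES}
    carboxyl = set(top.group("pops_carboxyl_oxygens").tolist())
    phosphate = set(top.group("pops_phosphate_oxygens").tolist())

    records: List[InteractionRecord] = []
    for fi in fidx:
        frame = trajectory.frame(int(fi))
        for pid in pids:
            donors = top.group(f"peptide{pid}_donors")
            carbons = top.group(f"peptide{pid}_nonpolar_carbons")
            lipidated = set(top.group(f"peptide{pid}_lipidated_carbons").tolist())
            n_hb: Dict[str, int] = {}
            hb_res_ps: set = set()
            class_ps = {"carboxyl": 0, "phosphate": 0}
            for sp in SPECIES:
                triples = detect_hydrogen_bonds(
                    frame, donors, acc[sp], top, criterion
                )
                n_hb[sp] = len(triples)
                if sp == "POPS":
                    for d, _h, a in triples:
                        hb_res_ps.add(int(top.residue_indices[d]))
                        if a in carboxyl:
                            class_ps["carboxyl"] += 1
                        elif a in phosphate:
                            class_ps["phosphate"] += 1
            n_c: Dict[str, int] = {}
            n_c_lip: Dict[str, int] = {}
            lip_arr = np.array(sorted(lipidated), dtype=int)
            for sp in SPECIES:
                n_c[sp] = count_vdw_contacts(frame, carbons, acyl[sp], contact_cutoff)
                n_c_lip[sp] = count_vdw_contacts(
                    frame, lip_arr, acyl[sp], contact_cutoff
                )
            records.append(
                InteractionRecord(
                    frame_index=int(fi),
                    peptide_id=pid,
                    n_hb=n_hb,
                    n_c=n_c,
                    n_c_lipidated=n_c_lip,
                    hb_residues_ps=tuple(sorted(hb_res_ps)),
                    hb_acceptor_class_ps=class_ps,
                )
            )
    return records


def records_to_frame(records: Sequence[InteractionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "frame": r.frame_index,
                "peptide": r.peptide_id,
                "N_HB_PC": r.n_hb["POPC"],
                "N_HB_PS": r.n_hb["POPS"],
                "N_C_PC": r.n_c["POPC"],
                "N_C_PS": r.n_c["POPS"],
                "N_C_PC_lipidated": r.n_c_lipidated["POPC"],
                "N_C_PS_lipidated": r.n_c_lipidated["POPS"],
                "HB_PS_carboxyl": r.hb_acceptor_class_ps["carboxyl"],
                "HB_PS_phosphate": r.hb_acceptor_class_ps["phosphate"],
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EnrichmentResult:
    mean_ps: float
    mean_pc: float
    n_pc: int
    n_ps: int
    fold: float
    rounded: int


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def enrichment_fold(
    mean_ps: float, mean_pc: float, n_pc: int, n_ps: int
) -> EnrichmentResult:
    """Composition-normalised PS enrichment: (mean_PS/mean_PC) x (n_PC/n_PS).

    ``n_pc``/``n_ps`` are the lipid counts of the peptide-hosting leaflet;
    a fold of 1 means interactions scale with composition (no sorting).
    """
    if mean_pc <= 0 or n_ps <= 0 or n_pc <= 0:
        raise PidrError(
            "enrichment undefined: mean_PC, n_PC and n_PS must be positive"
        )
    fold = (mean_ps / mean_pc) * (n_pc / n_ps)
    return EnrichmentResult(
        mean_ps=mean_ps,
        mean_pc=mean_pc,
        n_pc=n_pc,
        n_ps=n_ps,
        fold=fold,
        rounded=round_half_away(fold),
    )


def contribution_percent(part: float, total: float) -> float:
    """Percentage contribution of ``part`` to ``total`` (e.g. the
    non-lipidated sidechain share of the total contact count)."""
    if total <= 0:
        raise PidrError("total must be positive")
    return 100.0 * part / total


def residue_hb_frequency_map(
    records: Sequence[InteractionRecord],
    members: Optional[Iterable[Tuple[int, int]]] = None,
    residues: Optional[Sequence[int]] = None,
) -> Dict[int, float]:
    """Fraction of member conformers in which each residue forms >= 1
    hydrogen bond with POPS headgroup oxygens.

    ``members`` is an iterable of (frame_index, peptide_id) conformers
    (default: all records).  ``residues`` restricts/orders the output keys.
    """
    if members is not None:
        member_set = set(members)
        recs = [r for r in records if (r.frame_index, r.peptide_id) in member_set]
    else:
        recs = list(records)
    if not recs:
        raise PidrError("empty cluster membership")
    counts: Dict[int, int] = {}
    for r in recs:
        for resid in r.hb_residues_ps:
            counts[resid] = counts.get(resid, 0) + 1
    keys = list(residues) if residues is not None else sorted(counts)
    return {k: counts.get(k, 0) / len(recs) for k in keys}


def oxygen_site_preference(
    trajectory: Trajectory,
    criterion: HBCriterion = DEFAULT_HB,
    frame_mask: Optional[np.ndarray] = None,
) -> Dict[str, Tuple[int, int]]:
    """Per basic residue (Lys/Arg), total hydrogen-bond counts to POPS
    carboxyl vs phosphate oxygens over the masked frames (peptides pooled).

    Returns ``{"LYS185": (carboxyl, phosphate), ...}`` keyed by residue name
    + author number; an empty map when the peptides have no basic residues.
    """
    top = trajectory.topology
    carboxyl = top.group("pops_carboxyl_oxygens")
    phosphate = top.group("pops_phosphate_oxygens")
    if carboxyl.size == 0 and phosphate.size == 0:
        raise GroupError("POPS carboxyl/phosphate oxygen groups are undefined")
    if frame_mask is None:
        frame_mask = np.ones(trajectory.n_frames, dtype=bool)
    fidx = np.nonzero(frame_mask)[0]

    out: Dict[str, List[int]] = {}
    donor_is_basic: Dict[int, str] = {}
    for pid in top.peptide_ids:
        for d in top.group(f"peptide{pid}_donors"):
            resname = top.residue_names[d]
            if one_letter(resname) in BASIC_RESIDUES:
                label = f"{resname}{top.residue_indices[d]}"
                donor_is_basic[int(d)] = label
                out.setdefault(label, [0, 0])
    if not out:
        return {}

    basic_donors = np.array(sorted(donor_is_basic), dtype=int)
    for fi in fidx:
        frame = trajectory.frame(int(fi))
        for grp, slot in ((carboxyl, 0), (phosphate, 1)):
            for d, _h, _a in detect_hydrogen_bonds(
                frame, basic_donors, grp, top, criterion
            ):
                out[donor_is_basic[d]][slot] += 1
    return {k: (v[0], v[1]) for k, v in out.items()}


def summarize_interactions(
    records: Sequence[InteractionRecord],
    n_pc: int,
    n_ps: int,
) -> Dict[str, object]:
    """Means/SDs of the pooled per-conformer counts plus enrichment folds."""
    df = records_to_frame(records)
    out: Dict[str, object] = {}
    for col in ("N_HB_PC", "N_HB_PS", "N_C_PC", "N_C_PS"):
        out[f"{col}_mean"] = float(df[col].mean())
        out[f"{col}_sd"] = float(df[col].std(ddof=1)) if len(df) > 1 else 0.0
    try:
        hb = enrichment_fold(out["N_HB_PS_mean"], out["N_HB_PC_mean"], n_pc, n_ps)
        out["headgroup_enrichment_fold"] = hb.fold
        out["headgroup_enrichment_rounded"] = hb.rounded
    except PidrError:
        out["headgroup_enrichment_fold"] = None
    try:
        c = enrichment_fold(out["N_C_PS_mean"], out["N_C_PC_mean"], n_pc, n_ps)
        out["acyl_enrichment_fold"] = c.fold
        out["acyl_enrichment_rounded"] = c.rounded
    except PidrError:
        out["acyl_enrichment_fold"] = None
    nonlip_ps = float(
        (df["N_C_PS"] - df["N_C_PS_lipidated"]).mean()
        + (df["N_C_PC"] - df["N_C_PC_lipidated"]).mean()
    )
    total = out["N_C_PC_mean"] + out["N_C_PS_mean"]
    out["nonlipidated_contact_percent"] = (
        contribution_percent(nonlip_ps, total) if total > 0 else 0.0
    )
    return out
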