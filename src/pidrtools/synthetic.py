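"""Synthetic peptide-on-bilayer trajectories with known ground truth.

The generator emulates the study system -- an asymmetric bilayer with one
pure-POPC leaflet (108 lipids) and one mixed leaflet (77 POPC + 33 POPS),
three flexible peptides anchored by a deeply inserted prenyl chain -- as a
coarse geometric model: each lipid is ~10 named pseudo-atoms (phosphorus,
phosphate/carboxyl/ester oxygens, acyl-chain carbons) on a jittered lateral
lattice, and each peptide is a C-alpha chain with dummy sidechain, donor
and prenyl sites.  Backbone conformers are drawn per frame from a mixture
of discrete substates with prescribed radius of gyration and window
pseudo-dihedral, and per-species hydrogen-bond/contact counts are *planted*
by construction: designated lipid sites are moved into collinear 2.9 A
hydrogen-bond geometry or 3.8 A carbon-carbon contact geometry, while every
other inter-group distance is kept outside the detection cutoffs by
exclusion zones with margin.  Recovered counts therefore equal the planted
ground truth frame by frame, with no tolerance.

Nothing here is energetic or dynamical; the model exists to make every
analysis operation verifiable without molecular dynamics runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .groups import (
    NONPOLAR_RESIDUES,
    ONE_TO_THREE,
    POLAR_RESIDUES,
    THREE_TO_ONE,
    assign_groups,
)
from .membrane import (
    Frame,
    PidrError,
    Topology,
    Trajectory,
    center_of_mass,
    topology_from_metadata,
)
from .sequences import BUILTIN_ANCHORS, PIDRSequence


class PlantingError(PidrError):
    """Planted interactions could not be placed without violating exclusivity."""


# geometry constants (Angstrom); the margin analysis against the default
# 3.1 A / 30 deg hydrogen-bond and 4.0 A contact cutoffs is documented in
# docs/methods.md
CA_BOND = 3.8
HB_PLANT_DIST = 2.9
CONTACT_PLANT_DIST = 3.8
DONOR_EXCLUSION = 3.4  # planted acceptor keeps this distance to other donors
CARBON_EXCLUSION = 4.25  # planted carbon keeps this distance to other carbons
MIN_POLAR_OFFSET = 7.0  # polar sidechains lower than this risk stray HBs
MIN_NONPOLAR_OFFSET = -3.0
LIPID_EXCLUSION_RADIUS = 7.5  # lateral clearance around each prenyl column
MAX_JITTER = 0.5


@dataclass
class SubstateSpec:
    """One conformational substate of the planted mixture."""

    weight: float
    rg: float  # target C-alpha radius of gyration, Angstrom
    phi: float  # target pseudo-dihedral of the designated window, degrees
    n_hb: Dict[str, int] = field(default_factory=lambda: {"POPS": 5, "POPC": 3})
    n_c: Dict[str, int] = field(default_factory=lambda: {"POPS": 4, "POPC": 3})
    n_c_nonlipidated: Dict[str, int] = field(
        default_factory=lambda: {"POPS": 1, "POPC": 1}
    )
    z_offsets: Dict[int, float] = field(default_factory=dict)  # residue -> A
    jitter: float = 0.3  # coordinate jitter sigma, Angstrom
    carboxyl_cycle: Tuple[str, ...] = ("carboxyl", "carboxyl", "phosphate")
    orientation: float = 90.0  # backbone tilt from the membrane normal, deg

    def __post_init__(self) -> None:
        if not 0 <= self.weight <= 1:
            raise ValueError("substate weight must be in [0, 1]")
        if self.jitter > MAX_JITTER:
            raise ValueError(
                f"jitter sigma {self.jitter} exceeds the exclusion-margin "
                f"budget ({MAX_JITTER})"
            )
        for d in (self.n_hb, self.n_c, self.n_c_nonlipidated):
            if any(v < 0 for v in d.values()):
                raise ValueError("planted counts must be non-negative")
        for sp in ("POPS", "POPC"):
            if self.n_c_nonlipidated[sp] > self.n_c[sp]:
                raise ValueError("non-lipidated split exceeds the contact total")


DEFAULT_SUBSTATES = (
    SubstateSpec(weight=0.3, rg=9.3, phi=111.0),
    SubstateSpec(weight=0.7, rg=10.4, phi=-116.0),
)


@dataclass
class GroundTruth:
    """Everything the generator planted, for exact downstream checks."""

    substate_labels: np.ndarray  # (n_frames, n_peptides) int
    counts: Dict[str, np.ndarray]  # e.g. 'N_HB_POPS' -> (n_frames, n_peptides)
    hb_residues_ps: list  # [frame][peptide] -> tuple of residue numbers
    leaflet_labels: Dict[int, str]  # lipid molecule id -> mixed/pure
    apl: float  # the APL that area_per_lipid recovers (box area / n_pure)
    thickness: float  # planted P-P distance
    insertion_depth: float  # prenyl-COM depth of the un-jittered template
    phosphate_plane_z: float  # mean mixed-leaflet P z
    residue_offsets: List[Dict[int, float]]  # per substate: residue -> z offset
    phi_window: int
    substates: Tuple[SubstateSpec, ...]
    box: np.ndarray = field(default_factory=lambda: np.zeros(3))


# ----------------------------------------------------------------------
# Bilayer construction


@dataclass
class BilayerModel:
    topology: Topology
    frame: Frame
    ground_truth: GroundTruth
    # per-lipid bookkeeping used when peptides are merged in
    lipid_meta: List[Tuple[str, str, int, float, float]]  # species, leaflet, resid, x, y
    thickness: float


#: (name, dx, dy, dz) lipid site templates; dz is relative to the P atom for
#: the upper leaflet and mirrored for the lower.
_SITES_PC = [
    ("P", 0.0, 0.0, 0.0),
    ("OP1", 0.8, 0.0, 0.3),
    ("OP2", -0.8, 0.0, 0.3),
    ("OE1", 0.5, -0.5, -4.0),
    ("OE2", -0.5, 0.5, -4.0),
    ("CT1", 0.3, 0.3, -9.0),
    ("CT2", -0.3, 0.3, -11.5),
    ("CT3", 0.3, -0.3, -14.0),
    ("CT4", -0.3, -0.3, -16.5),
]
_SITES_PS = _SITES_PC + [
    ("OC1", 0.5, 0.5, 1.0),
    ("OC2", -0.5, 0.5, 1.0),
]


def build_bilayer(
    n_pc_pure: int = 108,
    n_pc_mixed: int = 77,
    n_ps_mixed: int = 33,
    apl: float = 64.0,
    thickness: float = 38.5,
    seed: int = 0,
    xy_jitter: float = 0.5,
    z_jitter: float = 0.3,
) -> BilayerModel:
    """Asymmetric coarse bilayer on a jittered square lattice.

    The mixed (POPS-containing) leaflet is the upper one; the box area is
    ``apl x max(leaflet counts)``.  POPS positions within the mixed leaflet
    are drawn under the seed; identical seeds give identical coordinates.
    """
    if apl <= 0 or thickness <= 0:
        raise ValueError("apl and thickness must be positive")
    rng = np.random.default_rng(seed)
    n_mixed = n_pc_mixed + n_ps_mixed
    n_max = max(n_mixed, n_pc_pure)
    box_l = math.sqrt(apl * n_max)
    box = np.array([box_l, box_l, 2.0 * thickness + 40.0])

    def lattice(n: int) -> np.ndarray:
        nx = math.ceil(math.sqrt(n))
        ny = math.ceil(n / nx)
        xs = (np.arange(nx) + 0.5) * box_l / nx
        ys = (np.arange(ny) + 0.5) * box_l / ny
        pts = np.array([(x, y) for y in ys for x in xs])[:n]
        return pts

    # lattice jitters are clipped at +/- 2 sigma (see the exclusion-margin
    # analysis in docs/methods.md)
    mixed_xy = lattice(n_mixed) + np.clip(
        rng.normal(0, xy_jitter, (n_mixed, 2)), -2 * xy_jitter, 2 * xy_jitter
    )
    pure_xy = lattice(n_pc_pure) + np.clip(
        rng.normal(0, xy_jitter, (n_pc_pure, 2)), -2 * xy_jitter, 2 * xy_jitter
    )
    species_mixed = np.array(["POPC"] * n_pc_mixed + ["POPS"] * n_ps_mixed)
    rng.shuffle(species_mixed)

    names: List[str] = []
    resnames: List[str] = []
    resids: List[int] = []
    chains: List[str] = []
    coords: List[Tuple[float, float, float]] = []
    lipid_meta: List[Tuple[str, str, int, float, float]] = []
    resid = 0
    z_half = thickness / 2.0
    for leaflet, xy_list, specs, sign in (
        ("mixed", mixed_xy, species_mixed, +1.0),
        ("pure", pure_xy, ["POPC"] * n_pc_pure, -1.0),
    ):
        for (x, y), sp in zip(xy_list, specs):
            resid += 1
            zp = sign * z_half + float(
                np.clip(rng.normal(0, z_jitter), -2 * z_jitter, 2 * z_jitter)
            )
            sites = _SITES_PS if sp == "POPS" else _SITES_PC
            for name, dx, dy, dz in sites:
                names.append(name)
                resnames.append(sp)
                resids.append(resid)
                chains.append("L")
                coords.append((x + dx, y + dy, zp + sign * dz))
            lipid_meta.append((sp, leaflet, resid, x, y))

    topology = topology_from_metadata(names, resnames, resids, chains)
    assign_groups(topology)
    frame = Frame(np.array(coords), box, time=0.0)

    labels = {}
    for mol in topology.lipid_ids:
        atom = np.nonzero(topology.molecule_ids == mol)[0][0]
        resid_of = int(topology.residue_indices[atom])
        labels[mol] = lipid_meta[resid_of - 1][1]
    p_idx = topology.group("lipid_P")
    mixed_p = [
        i for i in p_idx if labels[int(topology.molecule_ids[i])] == "mixed"
    ]
    plane_z = float(frame.coordinates[mixed_p, 2].mean())
    gt = GroundTruth(
        substate_labels=np.zeros((0, 0), dtype=int),
        counts={},
        hb_residues_ps=[],
        leaflet_labels=labels,
        apl=float(box[0] * box[1] / n_pc_pure),
        thickness=thickness,
        insertion_depth=0.0,
        phosphate_plane_z=plane_z,
        residue_offsets=[],
        phi_window=0,
        substates=(),
        box=box,
    )
    return BilayerModel(
        topology=topology,
        frame=frame,
        ground_truth=gt,
        lipid_meta=lipid_meta,
        thickness=thickness,
    )


# ----------------------------------------------------------------------
# Peptide templates


@dataclass
class PeptideTemplate:
    spec: SubstateSpec
    ca: np.ndarray  # (n_res, 3), local frame
    sequence: str
    anchor: PIDRSequence
    phi_window: int
    tau: float  # the uniform background torsion used


def _nerf(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _build_chain(n: int, tau: float, phi_window: int, phi: float) -> np.ndarray:
    """C-alpha chain with fixed bond length/angle and uniform torsion ``tau``
    except the designated window, whose torsion is ``phi``."""
    theta = math.radians(100.0)
    pts = [np.zeros(3), np.array([CA_BOND, 0.0, 0.0])]
    pts.append(
        pts[1]
        + CA_BOND
        * np.array([math.cos(math.pi - theta), math.sin(math.pi - theta), 0.0])
    )
    for i in range(3, n):
        torsion = phi if (i - 3) == phi_window else tau
        pts.append(
            _nerf(pts[i - 3], pts[i - 2], pts[i - 1], CA_BOND, theta, math.radians(torsion))
        )
    return np.array(pts)


def _chain_rg(pts: np.ndarray) -> float:
    c = pts - pts.mean(axis=0)
    return float(np.sqrt((c**2).sum(axis=1).mean()))


def build_peptide_templates(
    length: int,
    substates: Sequence[SubstateSpec],
    anchor: Optional[PIDRSequence] = None,
    phi_window: Optional[int] = None,
) -> List[PeptideTemplate]:
    """One backbone template per substate with exact target Rg and window
    pseudo-dihedral; the background torsion is found by a 1D root search."""
    if length < 4:
        raise PidrError("peptide templates need at least 4 residues")
    if anchor is None:
        anchor = BUILTIN_ANCHORS["Rap1B"]
    seq = anchor.sequence
    if len(seq) != length:
        raise PidrError(
            f"anchor sequence length {len(seq)} does not match length={length}"
        )
    if phi_window is None:
        phi_window = max(0, (length - 4) // 2)
    if not 0 <= phi_window <= length - 4:
        raise PidrError(f"phi_window {phi_window} out of range")

    templates = []
    taus = np.linspace(20.0, 179.0, 160)
    for spec in substates:
        rgs = np.array(
            [_chain_rg(_build_chain(length, t, phi_window, spec.phi)) for t in taus]
        )
        if not (rgs.min() - 0.05 <= spec.rg <= rgs.max() + 0.05):
            raise PidrError(
                f"target Rg {spec.rg} infeasible for length {length} "
                f"(reachable: {rgs.min():.2f}-{rgs.max():.2f})"
            )

        def f(t: float, target: float = spec.rg) -> float:
            return _chain_rg(_build_chain(length, t, phi_window, spec.phi)) - target

        tau_star = None
        fv = rgs - spec.rg
        for i in range(len(taus) - 1):
            if fv[i] == 0.0:
                tau_star = float(taus[i])
                break
            if fv[i] * fv[i + 1] < 0:
                tau_star = float(brentq(f, taus[i], taus[i + 1], xtol=1e-12))
                break
        if tau_star is None:
            tau_star = float(taus[int(np.argmin(np.abs(fv)))])
        ca = _build_chain(length, tau_star, phi_window, spec.phi)
        templates.append(
            PeptideTemplate(
                spec=spec,
                ca=ca,
                sequence=seq,
                anchor=anchor,
                phi_window=phi_window,
                tau=tau_star,
            )
        )
    return templates


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degree flip about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        perp -= a * np.dot(a, perp)
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (np.linalg.norm(v) ** 2))


def _orient_template(ca: np.ndarray, tilt_deg: float) -> np.ndarray:
    """Rotate so the N->C oriented principal axis makes ``tilt_deg`` with +z."""
    c = ca - ca.mean(axis=0)
    cov = c.T @ c
    _w, v = np.linalg.eigh(cov)
    axis = v[:, -1]
    if np.dot(axis, c[-1] - c[0]) < 0:
        axis = -axis
    target = np.array(
        [math.sin(math.radians(tilt_deg)), 0.0, math.cos(math.radians(tilt_deg))]
    )
    rot = _rotation_between(axis, target)
    return c @ rot.T


# ----------------------------------------------------------------------
# Peptide atom layout


def _peptide_atoms_for(
    template: PeptideTemplate,
) -> Tuple[List[Tuple[str, str, int]], Dict[str, np.ndarray]]:
    """Per-peptide atom metadata (name, resname, resid) and role index maps."""
    anchor = template.anchor
    seq = template.sequence
    numbering = anchor.numbering()
    meta: List[Tuple[str, str, int]] = []
    roles: Dict[str, List[int]] = {
        "ca": [], "cb": [], "nd": [], "hd": [], "prenyl": [], "palmitoyl": [],
    }
    n_prenyl = 15 if anchor.prenyl == "farnesyl" else 20
    for i, aa in enumerate(seq):
        resid = numbering[i]
        if i == len(seq) - 1:
            resname = "CYSF" if anchor.prenyl == "farnesyl" else "CYSG"
        elif resid in anchor.palmitoyl_positions:
            resname = "CYSP"
        else:
            resname = ONE_TO_THREE[aa]
        roles["ca"].append(len(meta))
        meta.append(("CA", resname, resid))
        if aa != "G":
            roles["cb"].append(len(meta))
            meta.append(("CB", resname, resid))
        if aa in POLAR_RESIDUES:
            roles["nd"].append(len(meta))
            meta.append(("ND", resname, resid))
            roles["hd"].append(len(meta))
            meta.append(("HD", resname, resid))
        if i == len(seq) - 1:
            for k in range(n_prenyl):
                roles["prenyl"].append(len(meta))
                meta.append((f"CP{k + 1}", resname, resid))
        if resid in anchor.palmitoyl_positions:
            for k in range(16):
                roles["palmitoyl"].append(len(meta))
                meta.append((f"CQ{k + 1}", resname, resid))
    return meta, {k: np.array(v, dtype=int) for k, v in roles.items()}


def _effective_offsets(template: PeptideTemplate) -> np.ndarray:
    """Per-residue sidechain z-offsets: spec overrides on top of defaults
    (+7.5 polar, +2.0 nonpolar), validated against the exclusion margins."""
    seq = template.sequence
    spec = template.spec
    numbering = template.anchor.numbering()
    out = np.zeros(len(seq))
    polar_rank = 0
    for i, aa in enumerate(seq):
        if aa in POLAR_RESIDUES:
            # stagger polar tiers so planted acceptors above one donor keep
            # clear of neighbouring donors
            default = 7.5 + 1.2 * (polar_rank % 2)
            polar_rank += 1
        else:
            default = 2.0
        off = spec.z_offsets.get(numbering[i], default)
        if aa in POLAR_RESIDUES and off < MIN_POLAR_OFFSET:
            raise PlantingError(
                f"polar residue {numbering[i]} offset {off} is below the "
                f"stray-HB exclusion minimum ({MIN_POLAR_OFFSET})"
            )
        if off < MIN_NONPOLAR_OFFSET:
            raise PlantingError(
                f"residue {numbering[i]} offset {off} is below the "
                f"stray-contact exclusion minimum ({MIN_NONPOLAR_OFFSET})"
            )
        out[i] = off
    return out


def _base_peptide_coords(
    template: PeptideTemplate,
    meta: List[Tuple[str, str, int]],
    roles: Dict[str, np.ndarray],
    origin_xy: np.ndarray,
    plane_z: float,
) -> np.ndarray:
    """Un-jittered coordinates of one peptide in one substate.

    The backbone floats above the phosphate plane (lowest C-alpha at
    plane + 3 A); sidechain sites (CB, and ND/HD for polar residues) are
    pinned at their planted z-offsets; the prenyl (and palmitoyl) chain
    drops vertically from the anchoring residue, with a widened 2 A gap
    before the terminal carbon so contacts planted at the tip touch only
    the tip.
    """
    spec = template.spec
    seq = template.sequence
    ca = _orient_template(template.ca, spec.orientation)
    # anchor the C-terminal (prenylated) residue at the lateral origin so
    # the prenyl column sits at the same spot in every substate
    ca[:, 0] += origin_xy[0] - ca[-1, 0]
    ca[:, 1] += origin_xy[1] - ca[-1, 1]
    ca[:, 2] += (plane_z + 3.0) - ca[:, 2].min()

    coords = np.zeros((len(meta), 3))
    coords[roles["ca"]] = ca
    # sidechains alternate sides of the chain (lateral perpendicular to the
    # local backbone direction) so that donor sites stay spread out
    n_res = ca.shape[0]
    cb_dir = np.zeros((n_res, 2))
    for i in range(n_res):
        a = ca[max(i - 1, 0), :2]
        b = ca[min(i + 1, n_res - 1), :2]
        t = b - a
        nt = np.linalg.norm(t)
        t = t / nt if nt > 1e-6 else np.array([1.0, 0.0])
        perp = np.array([-t[1], t[0]]) * (1.0 if i % 2 == 0 else -1.0)
        cb_dir[i] = perp

    offsets = _effective_offsets(template)
    i_cb = i_nd = 0
    cb_list = roles["cb"].tolist()
    nd_list = roles["nd"].tolist()
    hd_list = roles["hd"].tolist()
    for i, aa in enumerate(seq):
        z = plane_z + offsets[i]
        lateral = ca[i, :2] + 1.4 * cb_dir[i, :2]
        if aa != "G":
            coords[cb_list[i_cb]] = [lateral[0], lateral[1], z]
            i_cb += 1
        if aa in POLAR_RESIDUES:
            nd = np.array([lateral[0] + 0.6, lateral[1], z])
            coords[nd_list[i_nd]] = nd
            coords[hd_list[i_nd]] = nd + np.array([0.0, 0.0, 1.0])
            i_nd += 1
    n_pre = roles["prenyl"].size
    zs = np.concatenate(
        [np.linspace(plane_z - 5.0, plane_z - 13.0, n_pre - 1), [plane_z - 15.0]]
    )
    for k, idx in enumerate(roles["prenyl"]):
        coords[idx] = [ca[-1, 0], ca[-1, 1], zs[k]]
    n_palm = roles["palmitoyl"].size
    if n_palm:
        palm_res = template.anchor.palmitoyl_positions[0]
        i_palm = palm_res - template.anchor.start_residue
        zs_p = np.concatenate(
            [np.linspace(plane_z - 5.0, plane_z - 12.0, n_palm - 1), [plane_z - 14.0]]
        )
        for k, idx in enumerate(roles["palmitoyl"]):
            coords[idx] = [ca[i_palm, 0] + 0.5, ca[i_palm, 1], zs_p[k]]
    return coords


# ----------------------------------------------------------------------
# Exclusive placement of planted sites


def _candidate_dirs(axis: np.ndarray) -> List[np.ndarray]:
    """Deterministic candidate directions: the preferred axis, then rings of
    tilted fallbacks."""
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(float(np.dot(ref, axis))) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    dirs = [axis]
    for tilt in (15.0, 28.0, 45.0):
        st, ct = math.sin(math.radians(tilt)), math.cos(math.radians(tilt))
        for k in range(8):
            az = 2 * math.pi * k / 8
            dirs.append(ct * axis + st * (math.cos(az) * u + math.sin(az) * v))
    return dirs


def _place_exclusive(
    anchor_pos: np.ndarray,
    dist: float,
    axis: np.ndarray,
    avoid: np.ndarray,
    min_dist: float,
    start: int = 0,
) -> np.ndarray:
    """Point at ``dist`` from ``anchor_pos`` along a candidate direction, at
    least ``min_dist`` from every row of ``avoid``.  ``start`` rotates the
    candidate order so repeated placements spread out."""
    dirs = _candidate_dirs(axis)
    n = len(dirs)
    for k in range(n):
        d = dirs[(start + k) % n]
        pos = anchor_pos + dist * d
        if avoid.size == 0 or float(np.min(np.linalg.norm(avoid - pos, axis=1))) >= min_dist:
            return pos
    raise PlantingError(
        "could not place a planted interaction site without violating the "
        "exclusion margin; reduce planted counts or jitter"
    )


# ----------------------------------------------------------------------
# Trajectory emission


def emit_trajectory(
    bilayer: BilayerModel,
    templates: Sequence[PeptideTemplate],
    n_frames: int,
    frame_interval: float = 0.1,
    seed: int = 0,
    n_peptides: int = 3,
    counts_override: Optional[Dict[str, np.ndarray]] = None,
) -> Tuple[Trajectory, GroundTruth]:
    """Emit a trajectory with per-frame substate draws and planted counts.

    ``counts_override`` optionally replaces a planted count with a per-frame
    schedule, e.g. ``{"N_HB_POPS": array_of_len_n_frames}`` applied to every
    peptide -- used to emulate the headgroup-first sorting cascade.
    A single seeded random stream drives everything; identical seeds give
    byte-identical trajectories.
    """
    if n_frames <= 0:
        raise PidrError("n_frames must be positive")
    if not templates:
        raise PidrError("need at least one substate template")
    weights = np.array([t.spec.weight for t in templates], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise PidrError("substate weights must sum to 1")
    rng = np.random.default_rng(seed)

    # --- merged topology: peptides (chains A, B, ...) then lipids
    pep_meta, roles = _peptide_atoms_for(templates[0])
    names: List[str] = []
    resnames: List[str] = []
    resids: List[int] = []
    chains: List[str] = []
    chain_letters = [chr(ord("A") + i) for i in range(n_peptides)]
    for c in chain_letters:
        for nm, rn, ri in pep_meta:
            names.append(nm)
            resnames.append(rn)
            resids.append(ri)
            chains.append(c)
    lip_top = bilayer.topology
    names.extend(lip_top.names.tolist())
    resnames.extend(lip_top.residue_names.tolist())
    resids.extend(lip_top.residue_indices.tolist())
    chains.extend(lip_top.chain_ids.tolist())
    topology = topology_from_metadata(names, resnames, resids, chains)
    assign_groups(topology)

    n_pep_atoms = len(pep_meta)
    lip_off = n_peptides * n_pep_atoms
    box = bilayer.frame.box
    plane_z = bilayer.ground_truth.phosphate_plane_z

    fracs = [(0.25, 0.25), (0.75, 0.25), (0.5, 0.75), (0.25, 0.75), (0.75, 0.75)]
    if n_peptides > len(fracs):
        raise PidrError("at most 5 peptides supported")
    origins = [np.array([fx * box[0], fy * box[1]]) for fx, fy in fracs[:n_peptides]]

    base_pep = [
        [_base_peptide_coords(t, pep_meta, roles, origins[p], plane_z) for t in templates]
        for p in range(n_peptides)
    ]

    # push whole lipids laterally out of every lipid-chain column (prenyl
    # columns sit at the peptide origins; palmitoyl columns vary by
    # substate).  Leaflet membership, P z and therefore APL/thickness are
    # unaffected by lateral pushes.
    columns = list(origins)
    if roles["palmitoyl"].size:
        palm0 = int(roles["palmitoyl"][0])
        for p in range(n_peptides):
            for s in range(len(templates)):
                columns.append(base_pep[p][s][palm0, :2].copy())
    base_lipids = bilayer.frame.coordinates.copy()
    lip_resids = lip_top.residue_indices
    for sp, leaf, resid, x, y in bilayer.lipid_meta:
        for origin in columns:
            d = np.array([x, y]) - origin
            r = float(np.linalg.norm(d))
            if r < LIPID_EXCLUSION_RADIUS:
                direction = d / r if r > 1e-9 else np.array([1.0, 0.0])
                shift = (LIPID_EXCLUSION_RADIUS + 0.5 - r) * direction
                sel = lip_resids == resid
                base_lipids[sel, 0] += shift[0]
                base_lipids[sel, 1] += shift[1]
                x, y = x + shift[0], y + shift[1]
    pushed_meta = []
    for sp, leaf, resid, _x, _y in bilayer.lipid_meta:
        sel = np.nonzero(lip_resids == resid)[0]
        p_atom = sel[lip_top.names[sel] == "P"][0]
        pushed_meta.append((sp, leaf, resid, base_lipids[p_atom, 0], base_lipids[p_atom, 1]))

    pools = {
        sp: [m for m in pushed_meta if m[0] == sp and m[1] == "mixed"]
        for sp in ("POPS", "POPC")
    }
    site_idx: Dict[int, Dict[str, int]] = {}
    for sp, leaf, resid, _x, _y in pushed_meta:
        sel = np.nonzero(lip_resids == resid)[0]
        sites = {}
        for nm in ("OC1", "OP1", "CT1", "CT2"):
            hit = sel[lip_top.names[sel] == nm]
            if hit.size:
                sites[nm] = int(hit[0]) + lip_off
        site_idx[resid] = sites

    seq = templates[0].sequence
    numbering = templates[0].anchor.numbering()
    donors_local = roles["nd"].tolist()
    donor_to_hd = {int(d): int(h) for d, h in zip(roles["nd"], roles["hd"])}
    donor_resnum = {int(d): int(pep_meta[int(d)][2]) for d in donors_local}
    nonlip_anchor_local = [
        int(i)
        for i in roles["cb"]
        if THREE_TO_ONE[pep_meta[int(i)][1]] in NONPOLAR_RESIDUES
        and THREE_TO_ONE[pep_meta[int(i)][1]] != "P"
    ]
    prenyl_tip_local = int(roles["prenyl"][-1])
    all_donor_idx = np.concatenate(
        [np.asarray(donors_local, dtype=int) + p * n_pep_atoms for p in range(n_peptides)]
    )
    pep_carbons_by_pid = {
        p: topology.group(f"peptide{topology.peptide_ids[p]}_nonpolar_carbons")
        for p in range(n_peptides)
    }

    labels = np.zeros((n_frames, n_peptides), dtype=int)
    count_keys = (
        "N_HB_POPS", "N_HB_POPC", "N_C_POPS", "N_C_POPC",
        "N_C_POPS_nonlip", "N_C_POPC_nonlip",
        "HB_PS_carboxyl", "HB_PS_phosphate",
    )
    counts = {k: np.zeros((n_frames, n_peptides), dtype=int) for k in count_keys}
    hb_residues_ps: list = []
    all_coords = np.empty((n_frames, len(names), 3))
    up = np.array([0.0, 0.0, 1.0])
    down = -up

    for f in range(n_frames):
        coords = np.empty((len(names), 3))
        coords[lip_off:] = base_lipids
        frame_labels: List[int] = []
        for p in range(n_peptides):
            s = int(rng.choice(len(templates), p=weights))
            labels[f, p] = s
            frame_labels.append(s)
            sigma = templates[s].spec.jitter
            # jitter is clipped at +/- 2 sigma: the exclusion-zone margins
            # are proved for bounded displacements, and unbounded Gaussian
            # tails would (rarely) break planting exactness
            jit = np.clip(
                rng.normal(0, sigma, (n_pep_atoms, 3)), -2 * sigma, 2 * sigma
            )
            pep = base_pep[p][s] + jit
            coords[p * n_pep_atoms : (p + 1) * n_pep_atoms] = pep
        donor_positions = coords[all_donor_idx]

        frame_hb_res: list = []
        used = {"POPS": 0, "POPC": 0}
        for p in range(n_peptides):
            spec = templates[frame_labels[p]].spec
            n_hb = {
                sp: int(_sched(counts_override, f"N_HB_{sp}", f, spec.n_hb[sp]))
                for sp in ("POPS", "POPC")
            }
            n_c = {
                sp: int(_sched(counts_override, f"N_C_{sp}", f, spec.n_c[sp]))
                for sp in ("POPS", "POPC")
            }
            n_c_nonlip = {
                sp: min(spec.n_c_nonlipidated[sp], n_c[sp]) for sp in ("POPS", "POPC")
            }
            if n_hb["POPS"] + n_hb["POPC"] > len(donors_local):
                raise PlantingError(
                    f"planted HB counts exceed the {len(donors_local)} donor "
                    "sites of the peptide"
                )
            if max(n_c_nonlip.values()) > len(nonlip_anchor_local):
                raise PlantingError(
                    "planted non-lipidated contacts exceed available nonpolar "
                    "sidechain anchors"
                )
            for sp in ("POPS", "POPC"):
                if used[sp] + n_hb[sp] + n_c[sp] > len(pools[sp]):
                    raise PlantingError(
                        f"planted counts exceed available {sp} lipids in the "
                        "mixed leaflet"
                    )

            # ---- hydrogen bonds: collinear D-H...A along up-ish directions
            donor_order = [int(donors_local[k]) for k in rng.permutation(len(donors_local))]
            res_bonded: List[int] = []
            cls_counts = {"carboxyl": 0, "phosphate": 0}
            donor_iter = iter(donor_order)
            for sp in ("POPS", "POPC"):
                for j in range(n_hb[sp]):
                    # a donor whose surroundings are too crowded is skipped
                    # and the next one in the shuffled order is tried
                    while True:
                        try:
                            dl = next(donor_iter)
                        except StopIteration:
                            raise PlantingError(
                                "ran out of donor sites while planting "
                                "hydrogen bonds (peptide too crowded)"
                            ) from None
                        d_idx = dl + p * n_pep_atoms
                        d_pos = coords[d_idx]
                        other = donor_positions[all_donor_idx != d_idx]
                        try:
                            a_pos = _place_exclusive(
                                d_pos, HB_PLANT_DIST, up, other,
                                DONOR_EXCLUSION, start=j,
                            )
                            break
                        except PlantingError:
                            continue
                    u_vec = (a_pos - d_pos) / np.linalg.norm(a_pos - d_pos)
                    coords[donor_to_hd[dl] + p * n_pep_atoms] = d_pos + u_vec
                    lip = pools[sp][used[sp]]
                    used[sp] += 1
                    if sp == "POPS":
                        cls = spec.carboxyl_cycle[j % len(spec.carboxyl_cycle)]
                        site = "OC1" if cls == "carboxyl" else "OP1"
                        cls_counts[cls] += 1
                        res_bonded.append(donor_resnum[dl])
                    else:
                        site = "OP1"
                    coords[site_idx[lip[2]][site]] = a_pos

            # ---- vdW contacts: lipidated ones hang off the prenyl tip,
            # non-lipidated ones sit above nonpolar sidechain carbons
            pep_carb_idx = pep_carbons_by_pid[p]
            tip_idx = prenyl_tip_local + p * n_pep_atoms
            for sp in ("POPS", "POPC"):
                n_lip_contacts = n_c[sp] - n_c_nonlip[sp]
                tip = coords[tip_idx]
                avoid = coords[pep_carb_idx[pep_carb_idx != tip_idx]]
                for j in range(n_lip_contacts):
                    ct_pos = _place_exclusive(
                        tip, CONTACT_PLANT_DIST, down, avoid, CARBON_EXCLUSION,
                        start=j + (3 if sp == "POPC" else 0),
                    )
                    lip = pools[sp][used[sp]]
                    used[sp] += 1
                    coords[site_idx[lip[2]]["CT1"]] = ct_pos
                anchors = (
                    list(nonlip_anchor_local)
                    if sp == "POPS"
                    else list(reversed(nonlip_anchor_local))
                )
                anchor_iter = iter(anchors)
                for j in range(n_c_nonlip[sp]):
                    while True:
                        try:
                            al = next(anchor_iter)
                        except StopIteration:
                            raise PlantingError(
                                "ran out of nonpolar sidechain anchors while "
                                "planting contacts"
                            ) from None
                        a_idx = al + p * n_pep_atoms
                        anchor_pos = coords[a_idx]
                        avoid = coords[pep_carb_idx[pep_carb_idx != a_idx]]
                        try:
                            ct_pos = _place_exclusive(
                                anchor_pos, CONTACT_PLANT_DIST, up, avoid,
                                CARBON_EXCLUSION,
                            )
                            break
                        except PlantingError:
                            continue
                    lip = pools[sp][used[sp]]
                    used[sp] += 1
                    coords[site_idx[lip[2]]["CT2"]] = ct_pos

            counts["N_HB_POPS"][f, p] = n_hb["POPS"]
            counts["N_HB_POPC"][f, p] = n_hb["POPC"]
            counts["N_C_POPS"][f, p] = n_c["POPS"]
            counts["N_C_POPC"][f, p] = n_c["POPC"]
            counts["N_C_POPS_nonlip"][f, p] = n_c_nonlip["POPS"]
            counts["N_C_POPC_nonlip"][f, p] = n_c_nonlip["POPC"]
            counts["HB_PS_carboxyl"][f, p] = cls_counts["carboxyl"]
            counts["HB_PS_phosphate"][f, p] = cls_counts["phosphate"]
            frame_hb_res.append(tuple(sorted(set(res_bonded))))
        hb_residues_ps.append(frame_hb_res)
        all_coords[f] = coords

    # ---- ground truth
    leaflet_labels = {}
    for mol in topology.lipid_ids:
        atom = np.nonzero(topology.molecule_ids == mol)[0][0]
        resid_of = int(topology.residue_indices[atom])
        leaflet_labels[mol] = next(m[1] for m in pushed_meta if m[2] == resid_of)

    pid0 = topology.peptide_ids[0]
    residue_offsets: List[Dict[int, float]] = []
    for s, t in enumerate(templates):
        base0 = np.vstack([base_pep[0][s]] + [base_pep[p][s] for p in range(1, n_peptides)])
        full = np.vstack([base0, base_lipids])
        d: Dict[int, float] = {}
        for i, resid in enumerate(numbering):
            side = topology.group(f"peptide{pid0}_sidechain_r{resid}")
            if side.size == 0:
                ca = topology.group(f"peptide{pid0}_ca")
                side = ca[topology.residue_indices[ca] == resid]
            com = center_of_mass(full, side, topology.masses)
            d[int(resid)] = float(com[2] - plane_z)
        residue_offsets.append(d)

    prenyl_idx = topology.group(f"peptide{pid0}_prenyl_carbons")
    lipid_atoms = np.nonzero(topology.kinds == "lipid")[0]
    full0 = np.vstack(
        [np.vstack([base_pep[p][0] for p in range(n_peptides)]), base_lipids]
    )
    z_pre = center_of_mass(full0, prenyl_idx, topology.masses)[2]
    z_bil = center_of_mass(full0, lipid_atoms, topology.masses)[2]

    gt = GroundTruth(
        substate_labels=labels,
        counts=counts,
        hb_residues_ps=hb_residues_ps,
        leaflet_labels=leaflet_labels,
        apl=bilayer.ground_truth.apl,
        thickness=bilayer.thickness,
        insertion_depth=float(abs(z_pre - z_bil)),
        phosphate_plane_z=plane_z,
        residue_offsets=residue_offsets,
        phi_window=templates[0].phi_window,
        substates=tuple(t.spec for t in templates),
        box=box,
    )
    boxes = np.tile(box, (n_frames, 1))
    traj = Trajectory(topology, all_coords, boxes, frame_interval=frame_interval)
    return traj, gt


def _sched(
    override: Optional[Dict[str, np.ndarray]], key: str, f: int, default: int
) -> int:
    if override is not None and key in override:
        return int(override[key][f])
    return default


def make_reference_system(
    n_frames: int = 500,
    seed: int = 0,
    substates: Sequence[SubstateSpec] = DEFAULT_SUBSTATES,
    anchor: Optional[PIDRSequence] = None,
    n_peptides: int = 3,
    phi_window: Optional[int] = None,
    counts_override: Optional[Dict[str, np.ndarray]] = None,
    apl: float = 64.0,
    thickness: float = 38.5,
) -> Tuple[Trajectory, GroundTruth]:
    """Convenience: study-condition bilayer + peptides + trajectory.

    Defaults mirror the study conditions: 108 pure-leaflet POPC, 77 POPC +
    33 POPS in the mixed leaflet, three peptides, a two-substate 30/70
    conformer mixture, frames every 0.1 ns.
    """
    if anchor is None:
        anchor = BUILTIN_ANCHORS["Rap1B"]
    bilayer = build_bilayer(apl=apl, thickness=thickness, seed=seed)
    templates = build_peptide_templates(
        len(anchor.sequence), list(substates), anchor=anchor, phi_window=phi_window
    )
    return emit_trajectory(
        bilayer,
        templates,
        n_frames=n_frames,
        seed=seed + 1,
        n_peptides=n_peptides,
        counts_override=counts_override,
    )
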