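"""Reaction coordinates, 2D conformer densities and substate detection.

A membrane-bound disordered peptide is characterised per frame by global
coordinates -- radius of gyration (Rg), backbone RMSD after optimal
superposition, orientation of the backbone principal axis relative to the
membrane normal -- and a local coordinate: the pseudo-dihedral angle (Phi)
over four consecutive C-alpha atoms.  Conformational substates are peaks of
the smoothed 2D probability density P(RC, Phi), where RC is whichever global
coordinate (Rg or RMSD) is the more multimodal; substate membership is
"within one sigma of the peak" in both dimensions, with sigma the basin
standard deviation (circular for Phi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation

from .membrane import Frame, GroupError, PidrError, Topology, Trajectory


class DegenerateGeometryError(PidrError):
    """Geometry does not define the requested quantity."""


# ----------------------------------------------------------------------
# Per-frame geometry


def pseudo_dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC dihedral (degrees, in (-180, 180]) of four points.

    Built on virtual bonds p1-p2-p3-p4; positive when p4 is rotated
    clockwise looking down the p2->p3 axis.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if not (np.linalg.norm(b1) and np.linalg.norm(b2) and np.linalg.norm(b3)):
        raise DegenerateGeometryError("coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("three consecutive points are collinear")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    ang = np.degrees(np.arctan2(-y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def pseudo_dihedrals(points: np.ndarray) -> np.ndarray:
    """Vectorised dihedrals for an array of quadruples, shape (n, 4, 3)."""
    p = np.asarray(points, dtype=float)
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m, n2)
    ang = np.degrees(np.arctan2(-y, x))
    ang[np.isclose(ang, -180.0)] = 180.0
    return ang


def radius_of_gyration(
    frame: Frame,
    selection: np.ndarray,
    topology: Optional[Topology] = None,
    mass_weighted: bool = True,
) -> float:
    """sqrt(sum m_i |r_i - r_com|^2 / sum m_i) over the selection (Angstrom)."""
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise GroupError("empty selection for radius of gyration")
    coords = frame.coordinates[sel]
    if mass_weighted and topology is not None:
        w = topology.masses[sel]
    else:
        w = np.ones(sel.size)
    com = np.average(coords, axis=0, weights=w)
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=w)))


def backbone_rmsd(
    coords: np.ndarray, reference: np.ndarray
) -> float:
    """RMSD (Angstrom) after optimal rigid (Kabsch) superposition.

    Both arrays have shape (n, 3); atoms correspond one-to-one.
    """
    x = np.asarray(coords, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape:
        raise PidrError(
            f"atom count mismatch for RMSD: {x.shape} vs {y.shape}"
        )
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rot, _ = Rotation.align_vectors(yc, xc)
    diff = rot.apply(xc) - yc
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def orientation_angle(ca_coords: np.ndarray) -> float:
    """Angle (degrees, [0, 180]) between the N->C oriented first principal
    axis of the C-alpha coordinates and the membrane normal (+z)."""
    x = np.asarray(ca_coords, dtype=float)
    if x.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 C-alpha atoms")
    c = x - x.mean(axis=0)
    cov = c.T @ c
    if np.allclose(cov, 0):
        raise DegenerateGeometryError("all C-alpha atoms coincide")
    w, v = np.linalg.eigh(cov)
    axis = v[:, -1]
    # orient N -> C
    if np.dot(axis, x[-1] - x[0]) < 0:
        axis = -axis
    cosang = np.clip(axis[2] / np.linalg.norm(axis), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ----------------------------------------------------------------------
# Circular helpers (degrees)


def circular_mean(deg: np.ndarray) -> float:
    rad = np.radians(np.asarray(deg, dtype=float))
    s, c = np.sin(rad).mean(), np.cos(rad).mean()
    return float(np.degrees(np.arctan2(s, c)))


def circular_std(deg: np.ndarray) -> float:
    """Circular standard deviation in degrees (resultant-vector definition)."""
    rad = np.radians(np.asarray(deg, dtype=float))
    r = float(np.hypot(np.sin(rad).mean(), np.cos(rad).mean()))
    r = min(max(r, 1e-12), 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


def wrap_angle(deg) -> np.ndarray:
    """Wrap into (-180, 180]."""
    out = np.mod(np.asarray(deg, dtype=float) + 180.0, 360.0) - 180.0
    return np.where(out == -180.0, 180.0, out)


def circular_delta(a, b) -> np.ndarray:
    """Smallest signed angular difference a - b in degrees."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


# ----------------------------------------------------------------------
# Multimodality (dip-type) score


def dip_score(values: np.ndarray, n_modes: int = 64, max_points: int = 4000) -> float:
    """Dip-type multimodality score of a 1D sample.

    For each candidate mode m (a quantile grid over the data), the empirical
    CDF is fitted by its greatest convex minorant left of m and least concave
    majorant right of m -- the best unimodal-CDF shape with that mode -- and
    the sup-norm deviation is recorded.  The score is half the smallest such
    deviation over modes: ~0 for unimodal samples, large for well-separated
    multimodal ones.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 4:
        return 0.0
    if x.size > max_points:
        x = x[np.linspace(0, x.size - 1, max_points).astype(int)]
    n = x.size
    ecdf = (np.arange(1, n + 1)) / n
    mode_idx = np.unique(
        np.clip((np.linspace(0, 1, n_modes) * (n - 1)).astype(int), 0, n - 1)
    )
    best = np.inf
    for mi in mode_idx:
        dev_l = _hull_deviation(x[: mi + 1], ecdf[: mi + 1], convex=True)
        dev_r = _hull_deviation(x[mi:], ecdf[mi:], convex=False)
        best = min(best, max(dev_l, dev_r))
    return float(best / 2.0)


def _hull_deviation(x: np.ndarray, f: np.ndarray, convex: bool) -> float:
    """Sup deviation of (x, f) from its greatest convex minorant (convex) or
    least concave majorant (not convex)."""
    if x.size < 3:
        return 0.0
    # collapse ties in x, keeping extreme f
    ux, inv = np.unique(x, return_inverse=True)
    if ux.size < 3:
        return 0.0
    fu = np.full(ux.size, -np.inf if not convex else np.inf)
    if convex:
        np.minimum.at(fu, inv, f)
    else:
        np.maximum.at(fu, inv, f)
    pts = np.column_stack([ux, fu])
    sign = 1.0 if convex else -1.0
    hull: List[int] = []
    for i in range(pts.shape[0]):
        while len(hull) >= 2:
            o, a = pts[hull[-2]], pts[hull[-1]]
            cross = (a[0] - o[0]) * (pts[i, 1] - o[1]) - (a[1] - o[1]) * (
                pts[i, 0] - o[0]
            )
            if sign * cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    hx, hf = pts[hull, 0], pts[hull, 1]
    interp = np.interp(ux, hx, hf)
    return float(np.max(np.abs(fu - interp)))


def circular_dip_score(deg: np.ndarray) -> float:
    """Dip-type score for angles: the circle is cut at the largest gap
    between sorted angles (the sparsest region) and scored linearly."""
    a = np.sort(wrap_angle(deg))
    if a.size < 4:
        return 0.0
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    cut = int(np.argmax(gaps))
    rolled = np.concatenate([a[cut + 1 :], a[: cut + 1] + 360.0])
    return dip_score(rolled)


# ----------------------------------------------------------------------
# Descriptor tables


@dataclass
class ConformerDescriptor:
    frame_index: int
    peptide_id: int
    rg: float
    rmsd: float
    phi: float
    orientation: float


@dataclass
class DescriptorSeries:
    """Pooled per-conformer descriptors (one row per frame per peptide)."""

    frame_index: np.ndarray
    peptide_id: np.ndarray
    rg: np.ndarray
    rmsd: np.ndarray
    phi: np.ndarray
    orientation: np.ndarray
    phi_window: int

    @property
    def n(self) -> int:
        return self.frame_index.size

    def members(self, mask: np.ndarray) -> List[Tuple[int, int]]:
        return list(
            zip(self.frame_index[mask].tolist(), self.peptide_id[mask].tolist())
        )


def compute_descriptors(
    trajectory: Trajectory,
    frame_mask: Optional[np.ndarray] = None,
    phi_window: Optional[int] = None,
    rmsd_reference: Optional[Dict[int, np.ndarray]] = None,
) -> DescriptorSeries:
    """Per-frame, per-peptide reaction coordinates, pooled over peptides.

    ``phi_window`` is the index of the four-C-alpha window used for the
    pseudo-dihedral; when None it is chosen by :func:`choose_phi_quad`.
    The RMSD reference defaults to each peptide's first masked frame.
    """
    top = trajectory.topology
    if frame_mask is None:
        frame_mask = np.ones(trajectory.n_frames, dtype=bool)
    fidx = np.nonzero(frame_mask)[0]
    if fidx.size == 0:
        raise PidrError("empty frame mask")
    pids = top.peptide_ids
    if not pids:
        raise PidrError("no peptides in topology")

    if phi_window is None:
        phi_window, _ = choose_phi_quad(trajectory, frame_mask=frame_mask)

    rows_f, rows_p = [], []
    rg_all, rmsd_all, phi_all, ori_all = [], [], [], []
    for pid in pids:
        ca = top.group(f"peptide{pid}_ca")
        if ca.size < 4:
            raise PidrError(f"peptide {pid} has fewer than 4 C-alpha atoms")
        ref = (
            rmsd_reference[pid]
            if rmsd_reference is not None
            else trajectory.coordinates[fidx[0]][ca]
        )
        quad = ca[phi_window : phi_window + 4]
        coords = trajectory.coordinates[fidx][:, ca, :]
        phi = pseudo_dihedrals(trajectory.coordinates[fidx][:, quad, :])
        masses = top.masses[ca]
        com = np.average(coords, axis=1, weights=masses)
        sq = np.sum((coords - com[:, None, :]) ** 2, axis=2)
        rg = np.sqrt(np.average(sq, axis=1, weights=masses))
        rmsd = np.array([backbone_rmsd(c, ref) for c in coords])
        ori = np.array([orientation_angle(c) for c in coords])
        rows_f.append(fidx)
        rows_p.append(np.full(fidx.size, pid))
        rg_all.append(rg)
        rmsd_all.append(rmsd)
        phi_all.append(phi)
        ori_all.append(ori)
    return DescriptorSeries(
        frame_index=np.concatenate(rows_f),
        peptide_id=np.concatenate(rows_p),
        rg=np.concatenate(rg_all),
        rmsd=np.concatenate(rmsd_all),
        phi=np.concatenate(phi_all),
        orientation=np.concatenate(ori_all),
        phi_window=phi_window,
    )


def choose_global_rc(descriptors: DescriptorSeries) -> str:
    """Pick 'Rg' or 'RMSD' as the global reaction coordinate: whichever has
    the stronger dip-type multimodality score (ties go to Rg)."""
    if descriptors.n < 100:
        raise PidrError(
            f"need at least 100 conformers to choose a reaction coordinate "
            f"(got {descriptors.n})"
        )
    d_rg = dip_score(descriptors.rg)
    d_rmsd = dip_score(descriptors.rmsd)
    return "RMSD" if d_rmsd > d_rg else "Rg"


def choose_phi_quad(
    trajectory: Trajectory,
    frame_mask: Optional[np.ndarray] = None,
    weak_threshold: float = 0.02,
) -> Tuple[int, Dict[str, object]]:
    """Choose the four-consecutive-C-alpha window whose pseudo-dihedral best
    separates conformers, scored by the circular dip-type statistic.

    Returns ``(window_index, info)``; ``info['scores']`` holds all window
    scores and ``info['weak']`` flags the degenerate all-unimodal case.
    Ties go to the most C-terminal window.
    """
    top = trajectory.topology
    if frame_mask is None:
        frame_mask = np.ones(trajectory.n_frames, dtype=bool)
    fidx = np.nonzero(frame_mask)[0]
    pids = top.peptide_ids
    ca0 = top.group(f"peptide{pids[0]}_ca")
    n_win = ca0.size - 3
    if n_win < 1:
        raise PidrError("peptide too short for a pseudo-dihedral (need >= 4 residues)")
    scores = np.zeros(n_win)
    for w in range(n_win):
        phis = []
        for pid in pids:
            ca = top.group(f"peptide{pid}_ca")
            quad = ca[w : w + 4]
            phis.append(pseudo_dihedrals(trajectory.coordinates[fidx][:, quad, :]))
        scores[w] = circular_dip_score(np.concatenate(phis))
    best = int(np.nonzero(scores >= scores.max() - 1e-12)[0][-1])
    info = {"scores": scores, "weak": bool(scores.max() < weak_threshold)}
    if info["weak"]:
        warnings.warn(
            "no pseudo-dihedral window shows clear multimodality; "
            "classification is weak"
        )
    return best, info


# ----------------------------------------------------------------------
# 2D density and clusters


@dataclass
class Density2D:
    """Normalised probability density over (RC, Phi).

    ``values`` integrates to 1 over the grid; the Phi axis is periodic.
    """

    values: np.ndarray  # (n_rc, n_phi)
    rc_edges: np.ndarray
    phi_edges: np.ndarray
    rc_name: str = "RC"

    @property
    def rc_centers(self) -> np.ndarray:
        return 0.5 * (self.rc_edges[:-1] + self.rc_edges[1:])

    @property
    def phi_centers(self) -> np.ndarray:
        return 0.5 * (self.phi_edges[:-1] + self.phi_edges[1:])

    @property
    def cell_area(self) -> float:
        return float(
            (self.rc_edges[1] - self.rc_edges[0])
            * (self.phi_edges[1] - self.phi_edges[0])
        )


def _silverman_bw(x: np.ndarray) -> float:
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        return 0.0
    return 1.06 * scale * n ** (-1 / 5)


def density2d(
    rc_values: np.ndarray,
    phi_values: np.ndarray,
    grid: Tuple[int, int] = (100, 72),
    bandwidth: Optional[Tuple[float, float]] = None,
    rc_range: Optional[Tuple[float, float]] = None,
    rc_name: str = "RC",
) -> Density2D:
    """Smoothed, normalised 2D histogram density over (RC, Phi).

    The default grid is 100 RC bins x 72 Phi bins (5 degree Phi cells); the
    Phi axis is treated periodically both in binning and smoothing.
    Bandwidths default to Silverman's rule per dimension (circular SD for
    Phi).
    """
    rc = np.asarray(rc_values, dtype=float)
    phi = wrap_angle(np.asarray(phi_values, dtype=float))
    if rc.size == 0 or rc.size != phi.size:
        raise PidrError("rc and phi series must be equal-length and non-empty")
    n_rc, n_phi = grid
    if rc_range is None:
        lo, hi = float(rc.min()), float(rc.max())
        pad = 0.05 * (hi - lo) if hi > lo else max(0.5, 0.1 * abs(hi))
        rc_range = (lo - pad, hi + pad)
    rc_edges = np.linspace(rc_range[0], rc_range[1], n_rc + 1)
    phi_edges = np.linspace(-180.0, 180.0, n_phi + 1)
    hist, _, _ = np.histogram2d(rc, phi, bins=(rc_edges, phi_edges))
    if bandwidth is None:
        bw_rc = _silverman_bw(rc)
        sd_phi = circular_std(phi)
        bw_phi = 1.06 * sd_phi * phi.size ** (-1 / 5)
    else:
        bw_rc, bw_phi = bandwidth
    sig_rc = bw_rc / (rc_edges[1] - rc_edges[0])
    sig_phi = bw_phi / (phi_edges[1] - phi_edges[0])
    smoothed = gaussian_filter(
        hist, sigma=(max(sig_rc, 0.0), max(sig_phi, 0.0)), mode=("nearest", "wrap")
    )
    area = (rc_edges[1] - rc_edges[0]) * (phi_edges[1] - phi_edges[0])
    total = smoothed.sum() * area
    if total <= 0:
        raise PidrError("degenerate density (no counts)")
    return Density2D(smoothed / total, rc_edges, phi_edges, rc_name)


@dataclass
class EnsembleCluster:
    label: int
    center_rc: float
    center_phi: float
    sigma_rc: float
    sigma_phi: float
    member_mask: np.ndarray  # over the pooled conformer series
    occupancy: float  # 1-sigma-box members / total conformers
    basin_weight: float = 0.0  # watershed-basin conformers / total

    @property
    def n_members(self) -> int:
        return int(self.member_mask.sum())


def _local_maxima(values: np.ndarray) -> List[Tuple[int, int]]:
    """Strict-or-equal local maxima on a grid periodic along axis 1."""
    v = values
    peaks = []
    n_rc, n_phi = v.shape
    for i in range(n_rc):
        for j in range(n_phi):
            c = v[i, j]
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ii = i + di
                    jj = (j + dj) % n_phi
                    if 0 <= ii < n_rc and v[ii, jj] > c:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                peaks.append((i, j))
    return peaks


def _basins(values: np.ndarray) -> np.ndarray:
    """Steepest-ascent basin label per grid cell (periodic along axis 1).

    Cells follow their largest-valued neighbour uphill until a local
    maximum; the returned array holds the flat index of that maximum.
    """
    n_rc, n_phi = values.shape
    uphill = np.empty((n_rc, n_phi), dtype=int)
    for i in range(n_rc):
        for j in range(n_phi):
            best_v = values[i, j]
            best = i * n_phi + j
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii = i + di
                    jj = (j + dj) % n_phi
                    if 0 <= ii < n_rc and values[ii, jj] > best_v:
                        best_v = values[ii, jj]
                        best = ii * n_phi + jj
            uphill[i, j] = best
    flat = uphill.ravel()
    # pointer jumping until fixed point
    while True:
        nxt = flat[flat]
        if np.array_equal(nxt, flat):
            break
        flat = nxt
    return flat.reshape(n_rc, n_phi)


def find_clusters(
    density: Density2D,
    rc_values: np.ndarray,
    phi_values: np.ndarray,
    min_occupancy: float = 0.05,
    peak_threshold: float = 0.25,
    min_peak_to_uniform: float = 2.0,
) -> List[EnsembleCluster]:
    """Substate clusters from density peaks.

    Peaks are local maxima of the smoothed density above
    ``peak_threshold * max(density)`` and at least ``min_peak_to_uniform``
    times the uniform-density baseline (1 / grid area) -- structureless
    samples therefore yield no clusters.  Each peak's sigma per dimension is
    the standard deviation of the conformers in its steepest-ascent basin
    (circular for Phi); members are conformers within one sigma of the peak
    centre in both dimensions, with overlaps resolved to the nearer peak in
    sigma-normalised distance.  Occupancy is members / total conformers;
    clusters below ``min_occupancy`` are dropped.  Returns clusters sorted
    by occupancy (label 1 = most occupied); an empty list when nothing
    exceeds the threshold.
    """
    rc = np.asarray(rc_values, dtype=float)
    phi = wrap_angle(np.asarray(phi_values, dtype=float))
    v = density.values
    total_area = (
        (density.rc_edges[-1] - density.rc_edges[0])
        * (density.phi_edges[-1] - density.phi_edges[0])
    )
    uniform_level = 1.0 / total_area
    thresh = max(peak_threshold * v.max(), min_peak_to_uniform * uniform_level)
    peaks = [p for p in _local_maxima(v) if v[p] >= thresh]
    if not peaks:
        return []
    basins = _basins(v)
    n_phi = v.shape[1]
    peak_flat = {p[0] * n_phi + p[1]: p for p in peaks}

    # conformer -> grid cell
    rc_bin = np.clip(
        np.digitize(rc, density.rc_edges) - 1, 0, v.shape[0] - 1
    )
    phi_bin = np.clip(
        np.digitize(phi, density.phi_edges) - 1, 0, n_phi - 1
    )
    conformer_basin = basins[rc_bin, phi_bin]

    raw = []
    for flat, (pi, pj) in peak_flat.items():
        in_basin = conformer_basin == flat
        if in_basin.sum() < 2:
            continue
        c_rc = float(rc[in_basin].mean())
        c_phi = circular_mean(phi[in_basin])
        s_rc = float(np.std(rc[in_basin], ddof=1))
        s_phi = circular_std(phi[in_basin])
        if s_rc <= 0 or s_phi <= 0:
            continue
        raw.append((c_rc, c_phi, s_rc, s_phi, float(in_basin.mean())))
    if not raw:
        return []

    # 1-sigma box membership, overlaps to the nearer peak
    n = rc.size
    d2 = np.full((len(raw), n), np.inf)
    inbox = np.zeros((len(raw), n), dtype=bool)
    for k, (c_rc, c_phi, s_rc, s_phi, _bw) in enumerate(raw):
        drc = (rc - c_rc) / s_rc
        dphi = circular_delta(phi, c_phi) / s_phi
        inbox[k] = (np.abs(drc) <= 1.0) & (np.abs(dphi) <= 1.0)
        d2[k] = drc**2 + dphi**2
    assigned = np.where(inbox.any(axis=0), np.argmin(d2, axis=0), -1)

    clusters = []
    for k, (c_rc, c_phi, s_rc, s_phi, bw) in enumerate(raw):
        mask = (assigned == k) & inbox[k]
        occ = mask.sum() / n
        if occ < min_occupancy:
            continue
        clusters.append(
            EnsembleCluster(
                label=0,
                center_rc=c_rc,
                center_phi=c_phi,
                sigma_rc=s_rc,
                sigma_phi=s_phi,
                member_mask=mask,
                occupancy=float(occ),
                basin_weight=bw,
            )
        )
    clusters.sort(key=lambda c: -c.occupancy)
    for i, c in enumerate(clusters):
        c.label = i + 1
    return clusters


def equilibration_mask(trajectory: Trajectory, t_eq: float) -> np.ndarray:
    """Boolean mask of frames with time strictly greater than ``t_eq`` (ns).

    Emits a warning (and returns an all-False mask) when ``t_eq`` is at or
    beyond the end of the trajectory.
    """
    if t_eq < 0:
        raise PidrError("t_eq must be non-negative")
    mask = trajectory.times > t_eq
    if not mask.any():
        warnings.warn(
            f"equilibration time {t_eq} ns excludes every frame "
            f"(trajectory ends at {trajectory.times[-1]} ns)"
        )
    return mask
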