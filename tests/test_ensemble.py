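"""Reaction coordinates, multimodality scoring, densities and clusters."""

import math

import numpy as np
import pytest
from scipy.special import erf

from pidrtools import ensemble as E
from pidrtools.membrane import PidrError


# ----------------------------------------------------------------------
# pseudo-dihedral


@pytest.mark.parametrize(
    "pts,expected",
    [
        ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)], 0.0),  # cis
        ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)], 180.0),  # trans
        ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)], 90.0),
        ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, -1)], -90.0),
    ],
)
def test_pseudo_dihedral_reference_geometries(pts, expected):
    assert E.pseudo_dihedral(*pts) == pytest.approx(expected, abs=1e-9)


def _dihedral_projection_oracle(p1, p2, p3, p4):
    """Independent construction: project the flanking bonds onto the plane
    normal to the central bond; the dihedral is the angle between the
    projections, signed by the triple product."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    b2u = b2 / np.linalg.norm(b2)
    u = b1 - np.dot(b1, b2u) * b2u  # projection of the first virtual bond
    w = b3 - np.dot(b3, b2u) * b2u  # projection of the last virtual bond
    cosang = np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w))
    mag = 180.0 - math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
    triple = float(np.dot(np.cross(u, w), b2u))
    if mag == 0.0:
        return 0.0
    return mag if triple <= 0 else -mag


def test_pseudo_dihedral_matches_projection_oracle_on_random_quadruples():
    rng = np.random.default_rng(11)
    n = 10_000
    pts = rng.uniform(-5, 5, (n, 4, 3))
    fast = E.pseudo_dihedrals(pts)
    for k in range(n):
        p1, p2, p3, p4 = pts[k]
        ref = _dihedral_projection_oracle(p1, p2, p3, p4)
        diff = abs(E.circular_delta(fast[k], ref))
        assert diff < 1e-8, (k, fast[k], ref)


def test_pseudo_dihedral_antisymmetric_under_mirror():
    rng = np.random.default_rng(4)
    pts = rng.uniform(-3, 3, (200, 4, 3))
    mirrored = pts.copy()
    mirrored[:, :, 0] *= -1
    a = E.pseudo_dihedrals(pts)
    b = E.pseudo_dihedrals(mirrored)
    np.testing.assert_allclose(E.circular_delta(a, -b), 0.0, atol=1e-8)


def test_pseudo_dihedral_degenerate_inputs():
    with pytest.raises(E.DegenerateGeometryError):
        E.pseudo_dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
    with pytest.raises(E.DegenerateGeometryError):
        E.pseudo_dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


# ----------------------------------------------------------------------
# Rg / RMSD / orientation


def test_radius_of_gyration_reference_values(ref_traj):
    from pidrtools.membrane import Frame

    coords = np.zeros((ref_traj.topology.n_atoms, 3))
    frame = Frame(coords, np.array([50.0, 50, 50]))
    pid = ref_traj.topology.peptide_ids[0]
    ca = ref_traj.topology.group(f"peptide{pid}_ca")
    # all atoms coincident
    assert E.radius_of_gyration(frame, ca[:4]) == 0.0
    # two equal-mass points 4 A apart
    coords[ca[0]] = [0, 0, 0]
    coords[ca[1]] = [4, 0, 0]
    assert E.radius_of_gyration(Frame(coords, frame.box), ca[:2]) == pytest.approx(2.0)


def test_radius_of_gyration_brute_force_oracle(ref_traj):
    top = ref_traj.topology
    pid = top.peptide_ids[0]
    ca = top.group(f"peptide{pid}_ca")
    frame = ref_traj.frame(3)
    rg = E.radius_of_gyration(frame, ca, topology=top)
    m = top.masses[ca]
    com = np.zeros(3)
    for i, idx in enumerate(ca):
        com += m[i] * frame.coordinates[idx]
    com /= m.sum()
    acc = 0.0
    for i, idx in enumerate(ca):
        acc += m[i] * np.sum((frame.coordinates[idx] - com) ** 2)
    assert rg == pytest.approx(math.sqrt(acc / m.sum()), abs=1e-10)


def test_rmsd_rigid_transform_invariance():
    rng = np.random.default_rng(8)
    ref = rng.normal(0, 3, (19, 3))
    assert E.backbone_rmsd(ref, ref) == pytest.approx(0.0, abs=1e-10)
    from scipy.spatial.transform import Rotation

    for _ in range(20):
        rot = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
        moved = ref @ rot.T + rng.normal(0, 10, 3)
        assert E.backbone_rmsd(moved, ref) <= 1e-8


def test_rmsd_single_atom_displacement_bound():
    rng = np.random.default_rng(2)
    n = 19
    ref = rng.normal(0, 3, (n, 3))
    moved = ref.copy()
    moved[4] += [1.0, 0, 0]
    naive = math.sqrt(1.0 / n)
    fitted = E.backbone_rmsd(moved, ref)
    assert fitted <= naive + 1e-12
    assert fitted > 0


def test_rmsd_count_mismatch():
    with pytest.raises(PidrError):
        E.backbone_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


def test_orientation_reference_directions():
    z_chain = np.column_stack([np.zeros(10), np.zeros(10), np.arange(10.0)])
    assert E.orientation_angle(z_chain) == pytest.approx(0.0, abs=1e-8)
    x_chain = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
    assert E.orientation_angle(x_chain) == pytest.approx(90.0, abs=1e-8)
    with pytest.raises(E.DegenerateGeometryError):
        E.orientation_angle(np.zeros((5, 3)))


def test_orientation_recovers_planted_tilt():
    from pidrtools.synthetic import SubstateSpec, make_reference_system

    subs = (
        SubstateSpec(
            weight=1.0, rg=11.0, phi=100.0, orientation=30.0,
            n_hb={"POPS": 1, "POPC": 1}, n_c={"POPS": 1, "POPC": 1},
            n_c_nonlipidated={"POPS": 0, "POPC": 0},
        ),
    )
    traj, gt = make_reference_system(n_frames=40, seed=6, substates=subs)
    desc = E.compute_descriptors(traj, phi_window=gt.phi_window)
    assert np.mean(desc.orientation) == pytest.approx(30.0, abs=3.0)


# ----------------------------------------------------------------------
# multimodality and RC choice


def _series(rg, rmsd):
    n = rg.size
    return E.DescriptorSeries(
        frame_index=np.arange(n),
        peptide_id=np.zeros(n, dtype=int),
        rg=rg,
        rmsd=rmsd,
        phi=np.zeros(n),
        orientation=np.zeros(n),
        phi_window=0,
    )


def test_choose_global_rc_prefers_the_multimodal_coordinate():
    rng = np.random.default_rng(0)
    bimodal = np.concatenate([rng.normal(8, 0.2, 600), rng.normal(11, 0.2, 600)])
    unimodal = rng.normal(3, 0.4, 1200)
    assert E.choose_global_rc(_series(bimodal, unimodal)) == "Rg"
    assert E.choose_global_rc(_series(unimodal, bimodal)) == "RMSD"
    with pytest.raises(PidrError):
        E.choose_global_rc(_series(bimodal[:50], unimodal[:50]))


def test_dip_score_separates_clear_cases():
    rng = np.random.default_rng(1)
    uni = rng.normal(0, 1, 4000)
    bi = np.concatenate([rng.normal(-3, 0.5, 2000), rng.normal(3, 0.5, 2000)])
    assert E.dip_score(bi) > 5 * E.dip_score(uni)
    # circular variant: two genuinely separated circular modes vs one mode
    # straddling the +/-180 seam (which is unimodal on the circle)
    circ_bi = E.wrap_angle(
        np.concatenate([rng.normal(111, 12, 2000), rng.normal(-116, 12, 2000)])
    )
    circ_uni = E.wrap_angle(
        np.concatenate([rng.normal(175, 8, 2000), rng.normal(-175, 8, 2000)])
    )
    assert E.circular_dip_score(circ_bi) > 5 * E.circular_dip_score(circ_uni)


def test_choose_phi_quad_finds_the_planted_window(ref_traj, ref_gt):
    w, info = E.choose_phi_quad(ref_traj)
    assert w == ref_gt.phi_window
    assert not info["weak"]


def test_choose_phi_quad_four_residue_peptide_has_single_window():
    from pidrtools.sequences import PIDRSequence
    from pidrtools.synthetic import SubstateSpec, build_peptide_templates, build_bilayer, emit_trajectory

    anchor = PIDRSequence(
        name="mini", sequence="KKKC", start_residue=1, prenyl="farnesyl"
    )
    subs = [
        SubstateSpec(
            # a 4-residue chain has a single attainable Rg (~3.08 A): the
            # only torsion is the designated window itself
            weight=1.0, rg=3.08, phi=60.0,
            n_hb={"POPS": 1, "POPC": 0}, n_c={"POPS": 1, "POPC": 0},
            n_c_nonlipidated={"POPS": 0, "POPC": 0},
        )
    ]
    templates = build_peptide_templates(4, subs, anchor=anchor)
    bil = build_bilayer(seed=3)
    traj, _ = emit_trajectory(bil, templates, n_frames=20, seed=3, n_peptides=1)
    w, _info = E.choose_phi_quad(traj)
    assert w == 0  # the only four-C-alpha window


def test_choose_phi_quad_weak_flag_for_single_substate():
    from pidrtools.synthetic import SubstateSpec, make_reference_system

    subs = (
        SubstateSpec(
            weight=1.0, rg=10.0, phi=90.0,
            n_hb={"POPS": 1, "POPC": 1}, n_c={"POPS": 1, "POPC": 1},
            n_c_nonlipidated={"POPS": 0, "POPC": 0},
        ),
    )
    traj, _ = make_reference_system(n_frames=120, seed=13, substates=subs)
    with pytest.warns(UserWarning, match="weak"):
        _w, info = E.choose_phi_quad(traj)
    assert info["weak"]


# ----------------------------------------------------------------------
# density and clusters


def test_density_normalises_and_concentrates_single_point():
    rc = np.full(500, 9.0)
    phi = np.full(500, 40.0)
    d = E.density2d(rc, phi, bandwidth=(0.01, 1.0))
    assert d.values.sum() * d.cell_area == pytest.approx(1.0, rel=1e-9)
    imax = np.unravel_index(np.argmax(d.values), d.values.shape)
    assert abs(d.rc_centers[imax[0]] - 9.0) <= 2 * (d.rc_edges[1] - d.rc_edges[0])
    assert abs(d.phi_centers[imax[1]] - 40.0) <= 5.0


def test_density_uniform_phi_marginal_is_flat():
    rng = np.random.default_rng(10)
    rc = rng.normal(10, 0.5, 20000)
    phi = rng.uniform(-180, 180, 20000)
    d = E.density2d(rc, phi)
    marginal = d.values.sum(axis=0)
    marginal /= marginal.mean()
    assert np.abs(marginal - 1.0).max() < 0.15


def test_density_phi_periodicity():
    rng = np.random.default_rng(12)
    rc = rng.normal(10, 0.5, 3000)
    phi = rng.normal(170, 20, 3000)  # mass across the seam
    d1 = E.density2d(rc, phi, bandwidth=(0.2, 10.0))
    d2 = E.density2d(rc, phi + 360.0, bandwidth=(0.2, 10.0))
    np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)


def test_single_gaussian_cluster_matches_closed_form_box_mass():
    """Occupancy of a 1-sigma box around an isotropic Gaussian peak equals
    erf(1/sqrt(2))^2 = 0.466 (computed closed form), center within a cell."""
    rng = np.random.default_rng(21)
    n = 20000
    rc = rng.normal(10.0, 0.4, n)
    phi = rng.normal(30.0, 15.0, n)
    d = E.density2d(rc, phi)
    clusters = E.find_clusters(d, rc, phi)
    assert len(clusters) == 1
    c = clusters[0]
    expected = erf(1 / math.sqrt(2)) ** 2
    assert c.occupancy == pytest.approx(expected, abs=0.05)
    cell = d.rc_edges[1] - d.rc_edges[0]
    assert abs(c.center_rc - 10.0) <= cell + 3 * 0.4 / math.sqrt(n)
    assert abs(E.circular_delta(c.center_phi, 30.0)) <= 5.0
    assert c.basin_weight > 0.95


def test_two_substates_recover_weights_and_centers():
    rng = np.random.default_rng(33)
    n = 12000
    lab = rng.random(n) < 0.7
    rc = np.where(lab, rng.normal(10.4, 0.15, n), rng.normal(9.3, 0.15, n))
    phi = np.where(lab, rng.normal(-116, 10, n), rng.normal(111, 10, n))
    d = E.density2d(rc, phi)
    clusters = E.find_clusters(d, rc, phi)
    assert len(clusters) == 2
    c1, c2 = clusters
    assert c1.basin_weight == pytest.approx(0.7, abs=0.05)
    assert c2.basin_weight == pytest.approx(0.3, abs=0.05)
    assert c2.occupancy / c1.occupancy == pytest.approx(3 / 7, abs=0.05)
    cell = d.rc_edges[1] - d.rc_edges[0]
    assert abs(c1.center_rc - 10.4) <= cell
    assert abs(c2.center_rc - 9.3) <= cell
    # memberships are disjoint
    assert not (c1.member_mask & c2.member_mask).any()


def test_uniform_noise_yields_no_clusters():
    rng = np.random.default_rng(44)
    rc = rng.uniform(8, 12, 3000)
    phi = rng.uniform(-180, 180, 3000)
    d = E.density2d(rc, phi)
    clusters = E.find_clusters(d, rc, phi, min_occupancy=0.05)
    assert clusters == []


def test_cluster_of_everything_equals_unconditioned(ref_traj, ref_gt, ref_leaflets):
    """Conditioning on an all-frames cluster reproduces the pooled profile."""
    from pidrtools import bilayer as B

    pid = ref_traj.topology.peptide_ids[0]
    members = [(f, pid) for f in range(ref_traj.n_frames)]
    full = B.sidechain_z_profile(ref_traj, members, ref_leaflets)
    again = B.sidechain_z_profile(ref_traj, members, ref_leaflets)
    np.testing.assert_array_equal(full.mean, again.mean)


def test_partition_consistency_of_cluster_statistics(ref_traj, ref_gt):
    """Pooled mean equals the basin-weighted average of per-cluster means
    plus the unassigned remainder (checked on the Rg coordinate)."""
    desc = E.compute_descriptors(ref_traj, phi_window=ref_gt.phi_window)
    d = E.density2d(desc.rg, desc.phi)
    clusters = E.find_clusters(d, desc.rg, desc.phi)
    assigned = np.zeros(desc.n, dtype=bool)
    acc = 0.0
    for c in clusters:
        acc += desc.rg[c.member_mask].sum()
        assigned |= c.member_mask
    acc += desc.rg[~assigned].sum()
    assert acc / desc.n == pytest.approx(desc.rg.mean(), abs=1e-12)


# ----------------------------------------------------------------------
# equilibration


def test_equilibration_mask_thresholds(ref_traj):
    # frames are at 0.1 ns spacing starting at 0.1
    mask = E.equilibration_mask(ref_traj, 0.0)
    assert mask.all()
    mask = E.equilibration_mask(ref_traj, 0.45)
    assert mask.sum() == ref_traj.n_frames - 4
    with pytest.warns(UserWarning):
        empty = E.equilibration_mask(ref_traj, 1e6)
    assert not empty.any()
    with pytest.raises(PidrError):
        E.equilibration_mask(ref_traj, -1.0)


def test_ten_frame_example():
    """10 frames at 1 ns spacing, cut at 4 ns: 6 frames retained."""
    import pidrtools.membrane as M

    top = M.topology_from_metadata(["P"], ["POPC"], [1], ["L"])
    traj = M.Trajectory(
        top, np.zeros((10, 1, 3)), np.tile([10.0, 10, 10], (10, 1)),
        frame_interval=1.0,
    )
    mask = E.equilibration_mask(traj, 4.0)
    assert mask.sum() == 6
    assert list(np.nonzero(mask)[0]) == [4, 5, 6, 7, 8, 9]
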