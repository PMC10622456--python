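"""Hydrogen-bond/contact detection, species splits and enrichment folds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pidrtools import interactions as I
from pidrtools.groups import assign_groups
from pidrtools.membrane import (
    Frame,
    GroupError,
    PidrError,
    Topology,
    Trajectory,
    minimum_image_xy,
    topology_from_metadata,
)

BOX = np.array([40.0, 40.0, 80.0])


def _hb_topology(n_donors=1, n_acceptors=1):
    """Peptide serine donors (ND/HD) + POPS phosphate-oxygen acceptors."""
    names, resn, resi, chains = [], [], [], []
    for d in range(n_donors):
        for nm in ("CA", "ND", "HD"):
            names.append(nm)
            resn.append("SER")
            resi.append(d + 1)
            chains.append("A")
    for a in range(n_acceptors):
        for nm in ("P", "OP1"):
            names.append(nm)
            resn.append("POPS")
            resi.append(a + 1)
            chains.append("L")
    top = topology_from_metadata(names, resn, resi, chains)
    assign_groups(top)
    return top


def _hb_frame(top, donor_xyz, h_xyz, acceptor_xyz):
    coords = np.zeros((top.n_atoms, 3))
    nd = top.group("hb_donors")
    acc = top.group("hb_acceptors")
    for k, pos in enumerate(donor_xyz):
        coords[nd[k]] = pos
        coords[top.donor_hydrogens[int(nd[k])][0]] = h_xyz[k]
    for k, pos in enumerate(acceptor_xyz):
        coords[acc[k]] = pos
    return Frame(coords, BOX), nd, acc


@pytest.mark.parametrize(
    "acceptor,expected",
    [
        ((2.9, 0.0, 0.0), 1),  # collinear, inside both cutoffs
        ((3.2, 0.0, 0.0), 0),  # distance beyond 3.1
        ((3.0 / math.sqrt(2), 3.0 / math.sqrt(2), 0.0), 0),  # 45 deg off axis
        ((2.9 * math.cos(0.4), 2.9 * math.sin(0.4), 0.0), 1),  # ~23 deg, inside
    ],
)
def test_hb_geometry_criterion(acceptor, expected):
    top = _hb_topology()
    frame, nd, acc = _hb_frame(top, [(0, 0, 0)], [(1, 0, 0)], [acceptor])
    hbs = I.detect_hydrogen_bonds(frame, nd, acc, top)
    assert len(hbs) == expected


def test_hb_donor_without_hydrogen_is_configuration_error():
    top = _hb_topology()
    frame, nd, acc = _hb_frame(top, [(0, 0, 0)], [(1, 0, 0)], [(2.9, 0, 0)])
    top.donor_hydrogens = {}
    with pytest.raises(GroupError):
        I.detect_hydrogen_bonds(frame, nd, acc, top)


def _brute_force_hbs(frame, donors, acceptors, top, crit):
    out = []
    for d in donors:
        for a in acceptors:
            da = minimum_image_xy(
                frame.coordinates[a] - frame.coordinates[d], frame.box
            )
            if np.linalg.norm(da) > crit.d_cut:
                continue
            for h in top.donor_hydrogens[int(d)]:
                dh = minimum_image_xy(
                    frame.coordinates[h] - frame.coordinates[d], frame.box
                )
                cosang = np.dot(dh, da) / (np.linalg.norm(dh) * np.linalg.norm(da))
                if math.degrees(math.acos(np.clip(cosang, -1, 1))) <= crit.theta_cut:
                    out.append((int(d), int(h), int(a)))
    return sorted(out)


def test_hb_detection_equals_brute_force_on_random_frames():
    """Exact set equality against an O(N^2) loop oracle, random geometry."""
    top = _hb_topology(n_donors=6, n_acceptors=40)
    nd = top.group("hb_donors")
    acc = top.group("hb_acceptors")
    crit = I.HBCriterion()
    rng = np.random.default_rng(17)
    for trial in range(60):
        coords = np.zeros((top.n_atoms, 3))
        coords[nd] = rng.uniform([0, 0, 20], [40, 40, 28], (nd.size, 3))
        for d in nd:
            h = top.donor_hydrogens[int(d)][0]
            coords[h] = coords[d] + rng.normal(0, 0.7, 3)
        coords[acc] = rng.uniform([0, 0, 18], [40, 40, 30], (acc.size, 3))
        frame = Frame(coords, BOX)
        fast = I.detect_hydrogen_bonds(frame, nd, acc, top, crit)
        assert fast == _brute_force_hbs(frame, nd, acc, top, crit)


def test_hb_monotone_in_cutoffs():
    top = _hb_topology(n_donors=5, n_acceptors=30)
    nd, acc = top.group("hb_donors"), top.group("hb_acceptors")
    rng = np.random.default_rng(5)
    coords = np.zeros((top.n_atoms, 3))
    coords[nd] = rng.uniform(0, 10, (nd.size, 3))
    for d in nd:
        coords[top.donor_hydrogens[int(d)][0]] = coords[d] + rng.normal(0, 0.7, 3)
    coords[acc] = rng.uniform(0, 12, (acc.size, 3))
    frame = Frame(coords, BOX)
    prev = -1
    for d_cut in (2.0, 2.8, 3.1, 3.6, 4.5):
        n = len(I.detect_hydrogen_bonds(frame, nd, acc, top, I.HBCriterion(d_cut, 30)))
        assert n >= prev
        prev = n
    prev = -1
    for theta in (5.0, 15.0, 30.0, 60.0, 89.0):
        n = len(I.detect_hydrogen_bonds(frame, nd, acc, top, I.HBCriterion(3.1, theta)))
        assert n >= prev
        prev = n


def _contact_topology():
    names = ["CA", "CB", "CT1", "CT1"]
    resn = ["VAL", "VAL", "POPS", "POPC"]
    resi = [1, 1, 1, 2]
    chains = ["A", "A", "L", "L"]
    top = topology_from_metadata(names, resn, resi, chains)
    assign_groups(top)
    return top


@pytest.mark.parametrize("dist,expected", [(3.9, 1), (4.1, 0), (4.0, 1)])
def test_contact_cutoff_boundary(dist, expected):
    top = _contact_topology()
    coords = np.zeros((4, 3))
    coords[2] = [dist, 0, 0]  # PS acyl carbon near the CB at origin... CB idx?
    cb = top.group("peptide0_nonpolar_carbons")
    ps = top.group("acyl_carbons_POPS")
    pc = top.group("acyl_carbons_POPC")
    coords[ps[0]] = [dist, 0, 0]
    coords[pc[0]] = [20, 20, 0]
    frame = Frame(coords, BOX)
    assert I.count_vdw_contacts(frame, cb, ps) == expected
    assert I.count_vdw_contacts(frame, cb, pc) == 0


def test_contacts_monotone_in_cutoff():
    rng = np.random.default_rng(3)
    a = rng.uniform(0, 15, (12, 3))
    b = rng.uniform(0, 15, (40, 3))
    coords = np.vstack([a, b])
    names = ["CB"] * 12 + ["CT1"] * 40
    resn = ["VAL"] * 12 + ["POPS"] * 40
    resi = [1] * 12 + list(range(1, 41))
    chains = ["A"] * 12 + ["L"] * 40
    top = topology_from_metadata(names, resn, resi, chains)
    assign_groups(top)
    frame = Frame(coords, BOX)
    cb = top.group("peptide0_nonpolar_carbons")
    ps = top.group("acyl_carbons_POPS")
    counts = [I.count_vdw_contacts(frame, cb, ps, c) for c in (2, 3, 4, 6, 9)]
    assert counts == sorted(counts)


def test_interaction_timeseries_matches_ground_truth_exactly(ref_traj, ref_gt):
    records = I.interaction_timeseries(ref_traj)
    pidpos = {p: i for i, p in enumerate(ref_traj.topology.peptide_ids)}
    assert len(records) == ref_traj.n_frames * 3
    for r in records:
        p = pidpos[r.peptide_id]
        f = r.frame_index
        assert r.n_hb["POPS"] == ref_gt.counts["N_HB_POPS"][f, p]
        assert r.n_hb["POPC"] == ref_gt.counts["N_HB_POPC"][f, p]
        assert r.n_c["POPS"] == ref_gt.counts["N_C_POPS"][f, p]
        assert r.n_c["POPC"] == ref_gt.counts["N_C_POPC"][f, p]
        assert r.n_c_nonlipidated("POPS") == ref_gt.counts["N_C_POPS_nonlip"][f, p]
        assert r.n_c_nonlipidated("POPC") == ref_gt.counts["N_C_POPC_nonlip"][f, p]
        # species and lipidation splits are conservative by construction
        assert r.n_hb_total == r.n_hb["POPS"] + r.n_hb["POPC"]
        assert r.n_c_total == r.n_c["POPS"] + r.n_c["POPC"]


def test_timeseries_respects_frame_mask(ref_traj):
    mask = np.zeros(ref_traj.n_frames, dtype=bool)
    mask[10:20] = True
    records = I.interaction_timeseries(ref_traj, frame_mask=mask)
    assert {r.frame_index for r in records} == set(range(10, 20))
    with pytest.raises(PidrError):
        I.interaction_timeseries(ref_traj, frame_mask=np.zeros_like(mask))


@pytest.mark.parametrize(
    "mean_ps,mean_pc,fold,rounded",
    [
        (5.3, 3.0, 4.12, 4),  # headgroup sorting by the short Rho-family anchor
        (7.2, 10.1, 1.66, 2),  # acyl-chain sorting, same anchor
        (1.3, 1.1, 2.76, 3),  # the PBD-less control anchor
    ],
)
def test_enrichment_fold_printed_worked_examples(mean_ps, mean_pc, fold, rounded):
    res = I.enrichment_fold(mean_ps, mean_pc, n_pc=77, n_ps=33)
    assert res.fold == pytest.approx(fold, abs=0.005)
    assert res.rounded == rounded


def test_enrichment_errors():
    with pytest.raises(PidrError):
        I.enrichment_fold(1.0, 0.0, 77, 33)
    with pytest.raises(PidrError):
        I.enrichment_fold(1.0, 1.0, 77, 0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    x=st.floats(0.01, 100),
    n=st.integers(1, 500),
)
def test_enrichment_is_one_under_symmetry(x, n):
    assert I.enrichment_fold(x, x, n, n).fold == pytest.approx(1.0)


def test_round_half_away_from_zero():
    assert I.round_half_away(2.5) == 3
    assert I.round_half_away(3.49) == 3
    assert I.round_half_away(-2.5) == -3


def test_contribution_percent():
    assert I.contribution_percent(2.5, 11.2) == pytest.approx(22.32, abs=0.01)
    with pytest.raises(PidrError):
        I.contribution_percent(1.0, 0.0)


def test_residue_hb_frequency_trivial_and_ground_truth(ref_traj, ref_gt):
    records = I.interaction_timeseries(ref_traj)
    pidpos = {p: i for i, p in enumerate(ref_traj.topology.peptide_ids)}
    # recovered per-record residue sets equal the planted ones
    for r in records:
        assert r.hb_residues_ps == ref_gt.hb_residues_ps[r.frame_index][pidpos[r.peptide_id]]
    # frequency over all conformers matches the planted empirical frequency
    freq = I.residue_hb_frequency_map(records)
    n = len(records)
    for resid, f in freq.items():
        planted = sum(
            resid in ref_gt.hb_residues_ps[r.frame_index][pidpos[r.peptide_id]]
            for r in records
        )
        assert f == planted / n
        assert 0.0 <= f <= 1.0
    # uniform donor draws: each polar residue ~ n_hb_ps / n_donors
    n_donors = ref_traj.topology.group("peptide0_donors").size
    expected = 5.0 / n_donors  # both substates plant 5 PS bonds
    se = math.sqrt(expected * (1 - expected) / n)
    for f in freq.values():
        assert abs(f - expected) < 6 * se
    with pytest.raises(PidrError):
        I.residue_hb_frequency_map(records, members=[])


def test_oxygen_site_preference_recovers_planted_cycle(ref_traj, ref_gt):
    """The generator plants carboxyl:phosphate = 2:1 per PS bond cycle."""
    prefs = I.oxygen_site_preference(ref_traj)
    assert prefs  # Rap1B-like anchor has Lys/Arg residues
    tot_c = sum(v[0] for v in prefs.values())
    tot_p = sum(v[1] for v in prefs.values())
    planted_c = int(ref_gt.counts["HB_PS_carboxyl"].sum())
    planted_p = int(ref_gt.counts["HB_PS_phosphate"].sum())
    # the basic-residue subset of all planted PS bonds keeps the same sites;
    # totals over basic residues cannot exceed the planted totals
    assert tot_c <= planted_c and tot_p <= planted_p
    assert tot_c + tot_p > 0


def test_oxygen_preference_exact_on_basic_only_records(ref_traj, ref_gt):
    """Summing planted acceptor-class counts over all donors is exact."""
    records = I.interaction_timeseries(ref_traj)
    tot = {"carboxyl": 0, "phosphate": 0}
    for r in records:
        for k in tot:
            tot[k] += r.hb_acceptor_class_ps[k]
    assert tot["carboxyl"] == int(ref_gt.counts["HB_PS_carboxyl"].sum())
    assert tot["phosphate"] == int(ref_gt.counts["HB_PS_phosphate"].sum())
    # per-frame cycle C,C,P over 5 bonds -> exactly 4 carboxyl : 1 phosphate
    cyc = ref_gt.substates[0].carboxyl_cycle
    n_hb = ref_gt.substates[0].n_hb["POPS"]
    per_frame_c = sum(cyc[j % len(cyc)] == "carboxyl" for j in range(n_hb))
    assert tot["carboxyl"] * (n_hb - per_frame_c) == tot["phosphate"] * per_frame_c


def test_oxygen_preference_two_to_one_exact_on_noiseless_cycle():
    """Three PS bonds per frame under a C,C,P cycle give exactly 2:1."""
    from pidrtools.synthetic import SubstateSpec, make_reference_system

    subs = (
        SubstateSpec(
            weight=1.0, rg=9.5, phi=100.0,
            n_hb={"POPS": 3, "POPC": 1}, n_c={"POPS": 1, "POPC": 1},
            n_c_nonlipidated={"POPS": 0, "POPC": 0},
        ),
    )
    traj, gt = make_reference_system(n_frames=30, seed=2, substates=subs)
    records = I.interaction_timeseries(traj)
    tot_c = sum(r.hb_acceptor_class_ps["carboxyl"] for r in records)
    tot_p = sum(r.hb_acceptor_class_ps["phosphate"] for r in records)
    assert tot_c == 2 * tot_p
    assert tot_c + tot_p == 3 * len(records)


def test_sorting_cascade_headgroup_rise_precedes_acyl_rise():
    """When PS headgroup bonds ramp before PS contacts, the recovered series
    preserve the ordering (hydrogen bonds first, vdW contacts later)."""
    from pidrtools.synthetic import make_reference_system

    n = 60
    ramp_hb = np.where(np.arange(n) >= 15, 5, 0)
    ramp_c = np.where(np.arange(n) >= 35, 4, 0)
    traj, _gt = make_reference_system(
        n_frames=n,
        seed=9,
        counts_override={"N_HB_POPS": ramp_hb, "N_C_POPS": ramp_c},
    )
    records = I.interaction_timeseries(traj)
    df = I.records_to_frame(records).groupby("frame").mean()
    t_hb = df.index[df["N_HB_PS"] > 0].min()
    t_c = df.index[df["N_C_PS"] > 0].min()
    assert t_hb < t_c
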