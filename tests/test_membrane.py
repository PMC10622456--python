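"""Structure I/O, leaflet assignment and atom-group bookkeeping."""

import numpy as np
import pytest

from pidrtools import synthetic as S
from pidrtools.groups import assign_groups
from pidrtools.membrane import (
    Frame,
    ParseError,
    StructureError,
    Topology,
    Trajectory,
    GroupError,
    assign_leaflets,
    read_structure,
    select_group,
    topology_from_metadata,
    write_structure,
)

CRYST = "CRYST1   50.000   50.000   80.000  90.00  90.00  90.00 P 1           1\n"


def atom_line(serial, name, resname, chain, resid, x, y, z, element=None):
    name_f = f" {name:<3s}" if len(name) < 4 else name
    el = element or name[0]
    return (
        f"ATOM  {serial:5d} {name_f} {resname:<4s}{chain}{resid:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n"
    )


def model(i, lines):
    return f"MODEL {i:8d}\n" + "".join(lines) + "ENDMDL\n"


SINGLE_ATOM_PDB = (
    CRYST
    + model(1, [CRYST, atom_line(1, "P", "POPC", "L", 1, 12.345, 23.456, 7.890)])
    + "END\n"
)


def test_single_atom_single_model_reads_printed_fields(tmp_path):
    p = tmp_path / "one.pdb"
    p.write_text(SINGLE_ATOM_PDB)
    traj = read_structure(p, "pdb")
    assert traj.topology.n_atoms == 1
    assert traj.n_frames == 1
    np.testing.assert_allclose(
        traj.coordinates[0, 0], [12.345, 23.456, 7.890], atol=1e-6
    )
    np.testing.assert_allclose(traj.boxes[0], [50, 50, 80], atol=1e-6)
    atom = traj.topology.atoms[0]
    assert atom.molecule_kind.value == "lipid"
    assert atom.lipid_species.value == "POPC"


def test_three_models_share_one_topology(tmp_path):
    body = "".join(
        model(i, [CRYST, atom_line(1, "P", "POPC", "L", 1, 12.0 + i, 23.0, 7.0)])
        for i in (1, 2, 3)
    )
    p = tmp_path / "three.pdb"
    p.write_text(CRYST + body + "END\n")
    traj = read_structure(p, "pdb")
    assert traj.n_frames == 3
    assert traj.topology.n_atoms == 1
    np.testing.assert_allclose(traj.coordinates[:, 0, 0], [13.0, 14.0, 15.0], atol=1e-6)


def test_inconsistent_model_atom_counts_is_structural_error(tmp_path):
    text = (
        CRYST
        + model(1, [
            CRYST,
            atom_line(1, "P", "POPC", "L", 1, 12.0, 23.0, 7.0),
            atom_line(2, "P", "POPC", "L", 2, 13.0, 23.0, 7.0),
        ])
        + model(2, [CRYST, atom_line(1, "P", "POPC", "L", 1, 12.0, 23.0, 7.0)])
        + "END\n"
    )
    p = tmp_path / "bad.pdb"
    p.write_text(text)
    with pytest.raises(StructureError):
        read_structure(p, "pdb")


def test_malformed_coordinates_raise_parse_error_with_line(tmp_path):
    text = SINGLE_ATOM_PDB.replace("  12.345", "  xx.345")
    p = tmp_path / "mal.pdb"
    p.write_text(text)
    with pytest.raises(ParseError, match=r":4"):
        read_structure(p, "pdb")


def test_missing_file_raises(tmp_path):
    with pytest.raises(ParseError):
        read_structure(tmp_path / "nope.pdb")


@pytest.mark.parametrize("dialect,tol", [("pdb", 1.1e-3), ("xyz", 1e-5)])
def test_round_trip_preserves_metadata_and_coordinates(tiny_system, tmp_path, dialect, tol):
    traj, _gt = tiny_system
    path = tmp_path / f"sys.{dialect}"
    write_structure(traj, path, dialect)
    back = read_structure(path, dialect)
    top, btop = traj.topology, back.topology
    assert btop.n_atoms == top.n_atoms
    assert (btop.names == top.names).all()
    assert (btop.residue_names == top.residue_names).all()
    assert (btop.residue_indices == top.residue_indices).all()
    assert (btop.kinds == top.kinds).all()
    assert (btop.molecule_ids == top.molecule_ids).all()
    assert np.abs(back.coordinates - traj.coordinates).max() <= tol
    assert np.abs(back.boxes - traj.boxes).max() <= tol
    # groups rebuilt from atom names equal the generator's
    assign_groups(btop)
    for g in ("lipid_P", "hb_acceptors", "pops_carboxyl_oxygens", "acyl_carbons"):
        assert (btop.group(g) == top.group(g)).all()


def test_empty_frame_list_is_rejected(tiny_system):
    traj, _ = tiny_system
    with pytest.raises(StructureError):
        Trajectory(
            traj.topology,
            np.empty((0, traj.topology.n_atoms, 3)),
            np.empty((0, 3)),
        )


def _two_lipid_topology():
    names, resn, resi, chains = [], [], [], []
    for i, sp in enumerate(["POPS", "POPC"]):
        for nm in ("P", "CT1"):
            names.append(nm)
            resn.append(sp)
            resi.append(i + 1)
            chains.append("L")
    return topology_from_metadata(names, resn, resi, chains)


def test_leaflets_from_phosphorus_sign():
    top = _two_lipid_topology()
    coords = np.array(
        [[0, 0, 19.0], [0, 0, 10.0], [5, 5, -19.0], [5, 5, -10.0]]
    )
    frame = Frame(coords, np.array([50.0, 50, 80]))
    leaf = assign_leaflets(frame, top)
    # POPS (upper, P at +19) leaflet is the mixed one
    assert leaf.upper_is_mixed
    labels = list(leaf.labels.values())
    assert sorted(labels) == ["mixed", "pure"]


def test_leaflet_partition_matches_generator_ground_truth(ref_traj, ref_gt, ref_leaflets):
    assert ref_leaflets.labels == ref_gt.leaflet_labels
    counts = ref_leaflets.counts(ref_traj.topology)
    assert counts == {"mixed_POPS": 33, "mixed_POPC": 77, "pure_POPC": 108}
    n_lipids = len(ref_traj.topology.lipid_ids)
    assert sum(counts.values()) == n_lipids == 218


def test_lipid_without_phosphorus_is_named_in_error():
    names = ["CT1"]
    top = topology_from_metadata(names, ["POPS"], [1], ["L"])
    frame = Frame(np.zeros((1, 3)), np.array([10.0, 10, 10]))
    with pytest.raises(StructureError, match="phosphorus"):
        assign_leaflets(frame, top)


def test_select_group_contract(ref_traj):
    top = ref_traj.topology
    assert select_group(top, "lipid_P").size == 218
    with pytest.raises(GroupError):
        select_group(top, "no_such_group")


def test_farnesyl_prenyl_group_has_15_carbons():
    from pidrtools.sequences import BUILTIN_ANCHORS
    from pidrtools.synthetic import (
        SubstateSpec,
        build_bilayer,
        build_peptide_templates,
        emit_trajectory,
    )

    anchor = BUILTIN_ANCHORS["Rheb"]  # farnesylated
    subs = [SubstateSpec(weight=1.0, rg=7.0, phi=100.0,
                         n_hb={"POPS": 1, "POPC": 1}, n_c={"POPS": 1, "POPC": 1},
                         n_c_nonlipidated={"POPS": 0, "POPC": 0})]
    bil = build_bilayer(seed=1)
    tmpl = build_peptide_templates(len(anchor.sequence), subs, anchor=anchor)
    traj, _ = emit_trajectory(bil, tmpl, n_frames=1, seed=1, n_peptides=1)
    pid = traj.topology.peptide_ids[0]
    assert select_group(traj.topology, f"peptide{pid}_prenyl_carbons").size == 15


def test_group_chemistry_invariants(ref_traj):
    top = ref_traj.topology
    for pid in top.peptide_ids:
        nonpolar = top.group(f"peptide{pid}_nonpolar_carbons")
        elements = {top.atoms[i].element for i in nonpolar}
        assert elements == {"C"}
        # no proline carbons
        assert not any(top.residue_names[i] == "PRO" for i in nonpolar)
        # every donor has a bonded hydrogen
        for d in top.group(f"peptide{pid}_donors"):
            assert len(top.donor_hydrogens[int(d)]) >= 1
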