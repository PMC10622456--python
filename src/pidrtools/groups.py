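"""Atom-name -> analysis-group mapping.

The analyses never hard-code force-field atom names; they consume named
index groups on the :class:`~pidrtools.membrane.Topology`.  This module
builds those groups from a configurable table of atom-name rules with
defaults matching the naming scheme of the synthetic generator (CHARMM-like:
lipid phosphorus is ``P``, phosphate oxygens ``OP*``, the POPS carboxyl
oxygens ``OC*``, glycerol-ester oxygens ``OE*``, acyl-chain carbons ``CT*``;
peptide C-alpha ``CA``, sidechain carbon ``CB``, sidechain donor/hydrogen
``ND``/``HD``, prenyl carbons ``CP*``, palmitoyl carbons ``CQ*``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .membrane import GroupError, MoleculeKind, Topology

#: One-letter codes for the standard residues plus the modified cysteines
#: used in anchor models (CYSF farnesyl-Cys, CYSG geranylgeranyl-Cys, CYSP
#: palmitoyl-Cys).
THREE_TO_ONE: Dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "CYSF": "C", "CYSG": "C", "CYSP": "C",
}

ONE_TO_THREE: Dict[str, str] = {v: k for k, v in THREE_TO_ONE.items() if len(k) == 3}

#: Nonpolar (hydrophobic) residues, standard nonpolar class including Gly.
NONPOLAR_RESIDUES = frozenset("GAVLIPFMWC")
#: Residues whose sidechains can donate/accept hydrogen bonds (polar,
#: basic or acidic); these carry an ND/HD donor site in the coarse models.
POLAR_RESIDUES = frozenset("STNQYHKRDEW")
BASIC_RESIDUES = frozenset("KR")
ACIDIC_RESIDUES = frozenset("DE")


@dataclass
class GroupConfig:
    """Atom-name rules used to build analysis groups.

    Prefix tuples are matched against atom names with ``str.startswith``.
    ``acceptor_classes`` lists which lipid oxygen classes count as
    hydrogen-bond acceptors ("headgroup oxygen atoms").
    """

    lipid_p_names: Tuple[str, ...] = ("P",)
    phosphate_oxygen_prefixes: Tuple[str, ...] = ("OP",)
    carboxyl_oxygen_prefixes: Tuple[str, ...] = ("OC",)
    ester_oxygen_prefixes: Tuple[str, ...] = ("OE",)
    acyl_carbon_prefixes: Tuple[str, ...] = ("CT",)
    prenyl_carbon_prefixes: Tuple[str, ...] = ("CP",)
    palmitoyl_carbon_prefixes: Tuple[str, ...] = ("CQ",)
    backbone_ca_name: str = "CA"
    sidechain_carbon_name: str = "CB"
    donor_name: str = "ND"
    donor_hydrogen_name: str = "HD"
    acceptor_classes: Tuple[str, ...] = ("phosphate", "carboxyl", "ester")
    nonpolar_residues: frozenset = NONPOLAR_RESIDUES
    polar_residues: frozenset = POLAR_RESIDUES


DEFAULT_GROUP_CONFIG = GroupConfig()


def _starts(names: np.ndarray, prefixes: Tuple[str, ...]) -> np.ndarray:
    mask = np.zeros(len(names), dtype=bool)
    for p in prefixes:
        mask |= np.char.startswith(names.astype(str), p)
    return mask


def one_letter(residue_name: str) -> str:
    try:
        return THREE_TO_ONE[residue_name.upper()]
    except KeyError:
        raise GroupError(f"unknown peptide residue name {residue_name!r}") from None


def assign_groups(
    topology: Topology, config: Optional[GroupConfig] = None
) -> Topology:
    """Populate the standard analysis groups on ``topology`` (in place).

    Registered groups: ``lipid_P``, per-species ``headgroup_oxygens_*`` and
    ``acyl_carbons_*``, ``pops_phosphate_oxygens``, ``pops_carboxyl_oxygens``,
    ``ester_oxygens``, and per peptide molecule ``peptide{p}_ca``,
    ``peptide{p}_donors``, ``peptide{p}_nonpolar_carbons``,
    ``peptide{p}_lipidated_carbons``, ``peptide{p}_prenyl_carbons``,
    ``peptide{p}_palmitoyl_carbons`` and ``peptide{p}_sidechain_r{resid}``.
    The donor -> bonded-hydrogen map is filled alongside.
    """
    cfg = config or DEFAULT_GROUP_CONFIG
    names = topology.names
    kinds = topology.kinds
    species = topology.species

    lipid = kinds == MoleculeKind.lipid.value
    pep = kinds == MoleculeKind.peptide.value

    p_mask = lipid & np.isin(names, cfg.lipid_p_names)
    topology.register_group("lipid_P", np.nonzero(p_mask)[0])

    phos = lipid & _starts(names, cfg.phosphate_oxygen_prefixes)
    carb = lipid & _starts(names, cfg.carboxyl_oxygen_prefixes)
    ester = lipid & _starts(names, cfg.ester_oxygen_prefixes)
    acyl = lipid & _starts(names, cfg.acyl_carbon_prefixes)

    topology.register_group("pops_phosphate_oxygens", np.nonzero(phos & (species == "POPS"))[0])
    topology.register_group("pops_carboxyl_oxygens", np.nonzero(carb & (species == "POPS"))[0])
    topology.register_group("ester_oxygens", np.nonzero(ester)[0])
    topology.register_group("acyl_carbons", np.nonzero(acyl)[0])

    class_masks = {"phosphate": phos, "carboxyl": carb, "ester": ester}
    acceptor = np.zeros(topology.n_atoms, dtype=bool)
    for cname in cfg.acceptor_classes:
        acceptor |= class_masks[cname]
    topology.register_group("hb_acceptors", np.nonzero(acceptor)[0])
    for sp in ("POPC", "POPS"):
        topology.register_group(
            f"headgroup_oxygens_{sp}", np.nonzero(acceptor & (species == sp))[0]
        )
        topology.register_group(
            f"acyl_carbons_{sp}", np.nonzero(acyl & (species == sp))[0]
        )

    prenyl_all: list = []
    donor_map: Dict[int, list] = {}
    for pid in topology.peptide_ids:
        this = pep & (topology.molecule_ids == pid)
        idx = np.nonzero(this)[0]
        ca = idx[names[idx] == cfg.backbone_ca_name]
        topology.register_group(f"peptide{pid}_ca", ca)

        prenyl = idx[_starts(names[idx], cfg.prenyl_carbon_prefixes)]
        palm = idx[_starts(names[idx], cfg.palmitoyl_carbon_prefixes)]
        topology.register_group(f"peptide{pid}_prenyl_carbons", prenyl)
        topology.register_group(f"peptide{pid}_palmitoyl_carbons", palm)
        topology.register_group(
            f"peptide{pid}_lipidated_carbons", np.concatenate([prenyl, palm])
        )
        prenyl_all.extend(prenyl.tolist())

        nonpolar: list = []
        donors: list = []
        for resid in sorted(set(topology.residue_indices[idx].tolist())):
            ridx = idx[topology.residue_indices[idx] == resid]
            resname = topology.residue_names[ridx[0]]
            letter = one_letter(resname)
            side = ridx[
                (names[ridx] != cfg.backbone_ca_name)
                & (names[ridx] != cfg.donor_hydrogen_name)
            ]
            topology.register_group(f"peptide{pid}_sidechain_r{resid}", side)
            cb = ridx[names[ridx] == cfg.sidechain_carbon_name]
            # non-polar carbon set: excludes proline, includes the carbons of
            # lipidated cysteine chains (added above via prenyl/palmitoyl).
            if letter in cfg.nonpolar_residues and letter != "P":
                nonpolar.extend(cb.tolist())
            nd = ridx[names[ridx] == cfg.donor_name]
            hd = ridx[names[ridx] == cfg.donor_hydrogen_name]
            for d in nd:
                if hd.size == 0:
                    raise GroupError(
                        f"donor atom {d} (residue {resname}{resid}) has no "
                        f"bonded hydrogen {cfg.donor_hydrogen_name!r}"
                    )
                donors.append(int(d))
                donor_map[int(d)] = [int(h) for h in hd]
        nonpolar.extend(prenyl.tolist())
        nonpolar.extend(palm.tolist())
        topology.register_group(f"peptide{pid}_nonpolar_carbons", nonpolar)
        topology.register_group(f"peptide{pid}_donors", donors)

    topology.register_group("prenyl_carbons", prenyl_all)
    topology.register_group(
        "hb_donors",
        [d for pid in topology.peptide_ids for d in topology.group(f"peptide{pid}_donors")],
    )
    topology.set_donor_hydrogens(donor_map)
    return topology
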