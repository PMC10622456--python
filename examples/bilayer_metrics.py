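"""Bilayer structure and peptide depth profiles.

Computes the area per lipid (APL, from the pure-POPC leaflet), the P-P
bilayer thickness, the prenyl-chain insertion depth I, and the per-residue
sidechain depth profile relative to the phosphate plane of the
peptide-hosting leaflet.
"""

from pidrtools.bilayer import bilayer_timeseries, sidechain_z_profile
from pidrtools.membrane import assign_leaflets
from pidrtools.synthetic import make_reference_system

traj, truth = make_reference_system(n_frames=100, seed=2)
leaflets = assign_leaflets(traj.frame(0), traj.topology)

table = bilayer_timeseries(traj, leaflets)
pid = traj.topology.peptide_ids[0]
print(
    f"APL {table['APL'].mean():.2f} A^2, P-P {table['PP'].mean():.2f} A, "
    f"I(peptide {pid}) {table[f'I_peptide{pid}'].mean():.2f} A "
    f"(planted: APL {truth.apl:.2f}, P-P {truth.thickness:.1f})"
)

members = [(f, pid) for f in range(traj.n_frames)]
profile = sidechain_z_profile(traj, members, leaflets)
print("\nper-residue sidechain depth (A, + toward water, - into the bilayer):")
for resid, name, mean, sd in zip(
    profile.residues, profile.residue_names, profile.mean, profile.sd
):
    print(f"  {name:>4s}{resid}: {mean:+6.2f} +/- {sd:.2f}")
print(
    f"\nreference planes: phosphate {profile.phosphate_offset:+.1f}, "
    f"glycerol-ester oxygens {profile.ester_offset:+.2f}"
)
print(
    "\nThe prenylated cysteine is the only strongly inserted residue: its\n"
    "sidechain (Cys + prenyl chain) centre of mass sits ~9 A below the\n"
    "phosphate plane, while polar and basic sidechains stay on the solvent\n"
    "side."
)
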