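"""Conformational substates from a 2D (Rg, Phi) probability density.

The synthetic trajectory mixes two backbone substates (30% compact at
Rg = 9.3 A, window dihedral +111 deg; 70% extended at 10.4 A, -116 deg).
The analysis recovers them as peaks of the smoothed density, reports the
1-sigma memberships, and conditions the POPS hydrogen-bond frequency map
on each cluster.
"""

from pidrtools.ensemble import compute_descriptors, density2d, find_clusters
from pidrtools.interactions import interaction_timeseries, residue_hb_frequency_map
from pidrtools.synthetic import make_reference_system

traj, truth = make_reference_system(n_frames=800, seed=4)
desc = compute_descriptors(traj, phi_window=truth.phi_window)
density = density2d(desc.rg, desc.phi, rc_name="Rg")
clusters = find_clusters(density, desc.rg, desc.phi)

records = interaction_timeseries(traj)
for c in clusters:
    print(
        f"cluster {c.label}: center (Rg={c.center_rc:.2f} A, "
        f"Phi={c.center_phi:.0f} deg), sigma ({c.sigma_rc:.2f}, "
        f"{c.sigma_phi:.0f}), occupancy {c.occupancy:.2f}, "
        f"basin weight {c.basin_weight:.2f}"
    )
    freq = residue_hb_frequency_map(records, members=desc.members(c.member_mask))
    top3 = sorted(freq.items(), key=lambda kv: -kv[1])[:3]
    pretty = ", ".join(f"{r}:{f:.2f}" for r, f in top3)
    print(f"  most PS-bonded residues (fraction of member frames): {pretty}")

print()
print(
    "Occupancy counts conformers within 1 sigma of the peak in both\n"
    "dimensions (for a Gaussian substate that is ~47% of its frames);\n"
    "the basin weight is the full watershed share and recovers the planted\n"
    "30/70 mixture."
)
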