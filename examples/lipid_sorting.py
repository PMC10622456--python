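"""Lipid sorting statistics on a synthetic peptide-on-bilayer trajectory.

Generates a short ground-truth trajectory (asymmetric bilayer: 108 POPC in
one leaflet, 77 POPC + 33 POPS in the peptide-hosting leaflet; three
anchored peptides), counts hydrogen bonds and vdW contacts per peptide and
lipid species, and reports the composition-normalised PS enrichment folds.
"""

from pidrtools.interactions import interaction_timeseries, summarize_interactions
from pidrtools.membrane import assign_leaflets
from pidrtools.synthetic import make_reference_system

traj, truth = make_reference_system(n_frames=150, seed=1)
leaflets = assign_leaflets(traj.frame(0), traj.topology)
counts = leaflets.counts(traj.topology)
print(f"leaflet composition: {counts}")

records = interaction_timeseries(traj)
summary = summarize_interactions(
    records, n_pc=counts["mixed_POPC"], n_ps=counts["mixed_POPS"]
)
print(
    "mean per-peptide counts: "
    f"N_HB(PS)={summary['N_HB_PS_mean']:.2f} "
    f"N_HB(PC)={summary['N_HB_PC_mean']:.2f} "
    f"N_C(PS)={summary['N_C_PS_mean']:.2f} "
    f"N_C(PC)={summary['N_C_PC_mean']:.2f}"
)
print(
    f"PS enrichment: headgroup {summary['headgroup_enrichment_fold']:.2f}-fold "
    f"({summary['headgroup_enrichment_rounded']}-fold rounded), "
    f"acyl chains {summary['acyl_enrichment_fold']:.2f}-fold"
)
print()
print(
    "A fold of 1 would mean interactions scale with the 77:33 leaflet\n"
    "composition; folds above 1 indicate sorting of the anionic PS lipids\n"
    "toward the peptide.  Here the generator planted 5 PS vs 3 PC hydrogen\n"
    "bonds per peptide, i.e. a (5/3)x(77/33) = 3.9-fold headgroup preference."
)
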