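# pidrtools

Analysis of **prenylated intrinsically disordered regions (PIDRs)** — the
flexible, lipid-anchored C-terminal tails of small GTPases such as RhoA,
Rac1, Rap1A/B, Cdc42 and Rheb — adsorbed on asymmetric
phosphatidylcholine/phosphatidylserine (PC/PS) bilayers. The package is
aimed at molecular-simulation practitioners who want to quantify
*conformational-ensemble-dependent lipid recognition*: how the backbone
substates of a polybasic membrane anchor correlate with its sorting of
anionic PS lipids.

It provides, as a library with a thin CLI:

- **Bilayer metrics** — area per lipid `APL = Lx·Ly / n_lipids(pure
  leaflet)`, P–P thickness (distance between mean phosphorus planes),
  prenyl insertion depth `I = |z_COM(prenyl) − z_COM(bilayer)|`, and
  per-residue sidechain depth profiles relative to the host-leaflet
  phosphate plane.
- **Lipid-interaction statistics** — hydrogen bonds (donor–acceptor
  ≤ 3.1 Å, ≤ 30° off-linear at the donor) and carbon–carbon vdW contacts
  (≤ 4.0 Å) per peptide, split by lipid species, acceptor class
  (PS carboxyl vs phosphate) and lipidation; composition-normalised PS
  **enrichment folds** `(N(PS)/N(PC)) × (n_PC/n_PS)`.
- **Ensemble analysis** — per-conformer R_g, Kabsch RMSD, orientation, and
  Cα pseudo-dihedrals Φ; automatic choice of the multimodal global
  coordinate and the most classifying Φ window (dip-type statistic);
  smoothed 2D densities P(RC, Φ); substate clusters with 1σ membership,
  occupancies and per-cluster depth/H-bond conditioning.
- **Sequence descriptors** — polybasic-domain (PBD) identification
  (≥ 4 Lys/Arg separated by ≤ 2 other residues) and the descriptor set
  SL, Np, K:R, Nh, B:A, S for anchor sequences; the six study anchors are
  built in.
- **A synthetic trajectory generator** with exact ground truth (planted
  substates, depths and interaction counts) so the full pipeline is
  testable without running molecular dynamics.

Multi-model PDB (with CRYST1 boxes) is the native trajectory dialect,
parsed and written through MDAnalysis; a plain-text XYZ-with-box format is
supported for tiny fixtures.

## Worked example

```bash
python examples/lipid_sorting.py
```

```
leaflet composition: {'mixed_POPC': 77, 'mixed_POPS': 33, 'pure_POPC': 108}
mean per-peptide counts: N_HB(PS)=5.00 N_HB(PC)=3.00 N_C(PS)=4.00 N_C(PC)=3.00
PS enrichment: headgroup 3.89-fold (4-fold rounded), acyl chains 3.11-fold
```

The synthetic system plants 5 PS vs 3 PC hydrogen bonds per peptide on a
mixed leaflet of 77 PC / 33 PS. Because interactions are counted against a
leaflet with 2.3× more PC than PS, equal sorting would give a fold of 1;
the recovered `(5/3)·(77/33) = 3.89` (→ "4-fold") headgroup enrichment is
exactly the planted preference. `examples/conformational_substates.py`
recovers the planted two-substate mixture — centers (9.3 Å, +111°) and
(10.4 Å, −116°), basin weights 0.3/0.7 — and shows how per-residue PS
hydrogen-bond frequencies differ between clusters;
`examples/bilayer_metrics.py` and `examples/descriptor_table.py` cover the
bilayer observables and the Table-style descriptor scheme.

The same flow runs from the shell:

```bash
pidrtools synth --out sys.pdb --frames 200 --seed 1
pidrtools analyze --config config.yaml     # input/cutoffs/t_eq/outdir
pidrtools descriptors                      # built-in anchor table
pidrtools report --dir pidrtools_out
```

## Documentation

`docs/methods.md` describes the models, conventions, parameter defaults,
the synthetic generator's construction and its limits, and the numerical
choices in detail.
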