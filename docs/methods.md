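# Methods

`pidrtools` analyses trajectories of prenylated intrinsically disordered
regions (PIDRs) — the flexible, lipid-modified C-terminal membrane anchors
of small GTPases — adsorbed on an asymmetric phosphatidylcholine /
phosphatidylserine (PC/PS) bilayer. This note describes the models and
procedures the package implements, the choices made where the design was
genuinely open, and what the synthetic test system does and does not show
about real data.

## System model and conventions

A system is a `Topology` (atoms with molecule kind, residue identity and
named atom-index groups) plus a `Trajectory` of coordinates with
orthorhombic boxes. Conventions used throughout:

- the membrane normal is the +z axis, and the peptide-hosting ("mixed",
  PS-containing) leaflet is identified once from the sign of each lipid's
  phosphorus z relative to the lipid centre of mass — it is not re-detected
  per frame, because the anchors never translocate;
- the minimal-image convention is applied in x and y only. The bilayer is
  periodic laterally; wrapping z would create spurious contacts across the
  water slab;
- centres of mass are mass-weighted, with masses taken from a small element
  table (H, C, N, O, P, S, Na, Cl);
- internal atom indexing is 0-based; residue numbers from the input are
  preserved for reporting (anchor residues are conventionally numbered
  within the full-length protein, e.g. Arg185);
- default frame spacing is 0.1 ns, the usual trajectory-output stride for
  this kind of simulation, with the first frame at t = 0.1 ns.

Atom-name → group mapping (phosphorus, phosphate / carboxyl /
glycerol-ester oxygens, acyl-chain carbons, backbone Cα, sidechain sites,
donor–hydrogen pairs, prenyl and palmitoyl carbons) is a configurable table
(`GroupConfig`); force-field dialects differ, so no atom name is hard-coded
in the analyses. Hydrogen-bond acceptors default to all three lipid oxygen
classes; the carboxyl class exists only for PS, whose serine headgroup
carries the carboxylate that basic sidechains prefer.

## Bilayer metrics

- **Area per lipid (APL)** = lateral box area / number of lipids in the
  pure-PC leaflet, per frame. Values are instantaneous; downstream
  histogramming smooths them.
- **Thickness (P–P)** = mean z of upper-leaflet phosphorus minus mean z of
  lower-leaflet phosphorus.
- **Insertion depth (I)** = |z(COM of the prenyl chain) − z(COM of all
  lipid atoms)|.
- **Sidechain z-profiles**: per residue, mean ± SD (population SD, ddof=0,
  matching the worked reference values) of the sidechain-COM z relative to
  the mean phosphate z of the mixed leaflet; positive is toward water.
  Glycine has no sidechain and is reported from its backbone Cα. The
  prenylated cysteine's entry uses Cys + prenyl-chain atoms. The mean
  offsets of the POPS phosphate plane (0 by construction) and of the
  glycerol-ester oxygen plane are reported as reference lines.

## Lipid-interaction statistics

- **Hydrogen bonds**: a donor–hydrogen–acceptor triple qualifies when
  dist(D,A) ≤ 3.1 Å and the angle at the donor between D→H and D→A is
  ≤ 30°, i.e. ≤ 30° deviation from linearity — the common MD-analysis
  reading of a "donor–hydrogen–acceptor angle cutoff"; a literal interior
  D-H-A angle ≤ 30° would admit essentially no bonds at 3.1 Å. A hydrogen
  may satisfy several acceptors; each (D, H, A) triple counts once.
- **vdW contacts**: carbon–carbon pairs within 4.0 Å between non-polar
  sidechain carbons (excluding proline, including the lipidated-cysteine
  chains) and lipid acyl-chain carbons. Contacts count atom *pairs*, not
  lipid molecules, and are split by species and by lipidated vs
  non-lipidated peptide carbons.
- Pair search is a vectorised all-candidate distance computation over the
  (small) donor/acceptor and carbon groups; tests require exact set
  equality with an O(N²) Python-loop oracle.
- **Enrichment fold** = (mean per-peptide count with PS / with PC) ×
  (n_PC / n_PS of the mixed leaflet). A fold of 1 means interactions scale
  with composition; > 1 means PS sorting. The "n-fold" integer uses
  round-half-away-from-zero, which reproduces the conventional wording
  ("4-fold", "~2-fold") from the underlying means.
- **Residue HB frequency** (per conformational cluster) = fraction of
  member conformers in which a residue forms ≥ 1 hydrogen bond with POPS
  headgroup oxygens. The alternative per-maximum normalisation is not
  used; fractions are directly interpretable and bounded in [0, 1].
- **Oxygen-site preference**: hydrogen-bond totals of each Lys/Arg to POPS
  carboxyl vs phosphate oxygens.
- Records from the (up to three) peptides of a system are pooled per
  conformer, matching the practice of concatenating peptide copies;
  peptides whose anchor never inserted can be excluded by configuration
  (an optional, non-authoritative heuristic would be a mean lipid-chain
  depth above the phosphate plane; the package keeps exclusion explicit).

## Conformational-ensemble analysis

Per conformer (frame × peptide) the package computes: radius of gyration
(Rg, mass-weighted, over backbone Cα), backbone RMSD after optimal Kabsch
superposition (reference: each peptide's first analysed frame — RMSD time
series conventionally start near 0, implying an initial-structure
reference; a trajectory-average reference is configurable), the
orientation angle between the N→C-oriented first principal axis of the Cα
coordinates and +z, and the pseudo-dihedral Φ over a window of four
consecutive Cα atoms (signed IUPAC convention, verified against
MDAnalysis/biotite sign conventions and an independent plane-projection
construction).

**Choosing the coordinates.** The global reaction coordinate is whichever
of Rg and RMSD is more multimodal; the Φ window is the one whose dihedral
distribution most clearly splits the conformers. Both use a dip-type
multimodality score: the sup-norm distance between the empirical CDF and
its best fit by a CDF that is convex below a candidate mode and concave
above it, minimised over a quantile grid of candidate modes and halved. It
is ~0 for unimodal samples and grows with mode separation. For angles the
circle is cut at the widest gap in the sorted sample (the sparsest region)
before scoring, so modes straddling ±180° are not split. A window whose
best score stays below 0.02 (an empirically slack threshold; clear
bimodality scores more than an order of magnitude higher) is flagged as
"weak classification". Ties go to Rg and to the most C-terminal window.

**Density and substates.** P(RC, Φ) is a 2D histogram (default 100 RC bins
× 72 Φ bins of 5°) smoothed with a Gaussian kernel, Silverman's-rule
bandwidth per dimension (circular SD for Φ), periodic along Φ, normalised
to integrate to 1. Substates are local maxima above 25% of the density
maximum *and* above twice the uniform baseline (1/grid-area) — the second
guard makes structureless samples yield no clusters. Each peak's σ per
dimension is the standard deviation (circular for Φ) of the conformers in
its steepest-ascent watershed basin; cluster **members** are conformers
within 1σ of the peak centre in both dimensions, with overlaps resolved to
the nearer peak in σ-normalised distance. Two weights are reported:
**occupancy** (members / total conformers; ≈ 0.466 of a Gaussian
substate's mass, since erf(1/√2)² of it falls in the ±1σ box) and
**basin weight** (basin conformers / total), which estimates the mixture
weight itself. The printed "± values" of cluster centres are basin SDs,
not fit parameters. All peaks above threshold are reported on a single
density (no hierarchical re-clustering).

**Equilibration.** Analyses exclude frames with time ≤ t_eq; per-system
defaults (0.5 µs for the two short anchors, 1 µs for the three long ones,
2.2 µs for the palmitoylated one) ship with the configuration schema.

The whole analysis chain is deterministic given its configuration — there
is no stochastic step — so a rerun reproduces every artifact byte for
byte, and the report carries a provenance hash of configuration + inputs.

## Sequence descriptors

A polybasic domain (PBD) is a maximal run of Lys/Arg residues, grown
N→C while consecutive basic residues are separated by at most two
non-basic residues, trimmed to start and end on a basic residue, and
qualifying with ≥ 4 basic residues; when several runs qualify the
C-terminal-most is taken (PBDs function adjacent to the prenylation site).
Descriptors: SL (length), Np (= K + R, basic residues in the PBD), K:R,
Nh (hydrophobic fraction strictly N-terminal to the PBD), B:A
(basic:acidic counts in the same region), and S (residues strictly between
the last PBD residue and the prenylated cysteine). The hydrophobic set is
the standard non-polar residue class {G, A, V, L, I, P, F, M, W, C}; with
this set every reference Nh value is reproduced from the sequences alone
(one reported fraction, 9/13, prints as 0.69 here vs a rounded 0.70
elsewhere). Basic = {K, R} (His excluded), acidic = {D, E}. All sets are
configurable.

The six built-in anchor sequences follow the canonical human C-termini of
Rheb, RhoA, Rap1A, Rap1B, Rac1 and Cdc42b; the Rheb entry's interior is a
partial reconstruction (see its docstring) and no reference descriptor
value depends on it.

## The synthetic trajectory generator

The generator exists to make every analysis stage testable without
molecular dynamics. It emulates the study conditions as a coarse geometric
model:

- an asymmetric bilayer of 218 lipids — 108 PC in the pure leaflet,
  77 PC + 33 PS in the mixed (upper) leaflet — on a jittered square
  lattice with box area = APL × max(leaflet count); default APL 64 Å² and
  P–P thickness 38.5 Å, typical fluid-PC values. Each lipid is ~10 named
  pseudo-atoms (P; phosphate, carboxyl [PS only] and ester oxygens; four
  acyl carbons);
- three peptides whose Cα backbones are built by internal-coordinate
  chain construction (bond 3.8 Å, angle 100°): all background torsions
  equal a value found by 1D root search so the chain's Rg hits the
  substate's target exactly, while the designated window torsion is set to
  the target Φ. Sidechain/donor/prenyl sites are pseudo-atoms; sidechain
  z-offsets are pinned per residue (defaults: polar ≥ +7.5 Å, nonpolar
  +2 Å);
- per frame, each peptide's substate is drawn from the specified mixture
  (default 30% at Rg 9.3 Å / Φ +111° and 70% at 10.4 Å / −116°, echoing a
  two-substate conformer ensemble), and the template is jittered with
  Gaussian noise of σ = 0.3 Å **clipped at ±2σ** — the planting-exactness
  margins below are proved for bounded displacements;
- planted interactions: hydrogen bonds are created by moving a designated
  lipid oxygen into collinear geometry 2.9 Å from a donor (inside the
  3.1 Å / 30° criterion), vdW contacts by moving a designated acyl carbon
  to 3.8 Å from a peptide carbon (inside 4.0 Å). Defaults per peptide per
  frame: 5 PS / 3 PC hydrogen bonds, 4 PS / 3 PC contacts (one of each
  species' contacts through a non-lipidated sidechain carbon), and a
  carboxyl:phosphate acceptor cycle of 2:1 for PS bonds. Donors are drawn
  uniformly per frame, so each polar residue's planted HB frequency is
  n_HB(PS)/n_donors;
- exactness by exclusion zones: every non-planted distance is kept outside
  the cutoffs with margin — lipids are pushed laterally out of a 7.5 Å
  column around each prenyl/palmitoyl chain, polar sidechains sit ≥ 7 Å
  above the phosphate plane (headgroup oxygens reach at most ~+1.6 Å),
  non-polar sidechains stay ≥ −3 Å (acyl carbons start at −9 Å), the
  prenyl chain ends in a widened 2 Å tip gap so tip-planted contacts touch
  only the tip, and every planted site is verified against a candidate
  direction set (straight + three tilt rings) to keep ≥ 3.4 Å from other
  donors / ≥ 4.25 Å from other carbons, skipping to another donor or
  anchor when a neighbourhood is too crowded. Recovered counts therefore
  equal the planted ground truth frame by frame with no tolerance;
- a single seeded random stream drives everything; identical seeds give
  byte-identical trajectories. Optional per-frame count schedules emulate
  the headgroup-first sorting cascade (PS hydrogen bonds rising before PS
  acyl contacts).

**What passing tests show — and what they do not.** The generator plants
discrete substates with small isotropic jitter, static lipids, and
interaction counts that are decided, not emergent. Tests against it verify
that the *measurement* chain is exact and unbiased: detection geometry,
species and lipidation splits, composition normalisation, density peaks,
basin weights, per-cluster conditioning. They say nothing about force
fields, sampling convergence, or whether real anchors sort lipids — on
real trajectories the same code measures whatever the physics produced.
Known idealisations: no water/ions (no analysis consumes them), lipids are
not chemically complete, peptide substates are rigid templates rather than
a continuous ensemble, and the planted geometry is chemically arbitrary
wherever that does not affect a measured quantity.

## Numerical notes and degenerate inputs

- Dihedrals are undefined for coincident/collinear consecutive points and
  raise; Φ = 180° is returned in place of −180°.
- Kabsch superposition uses `scipy`'s rotation alignment; rigid-transform
  invariance holds to ≤ 1e−8 Å.
- Circular means/SDs use the resultant-vector definitions; cluster centres
  near ±180° do not split.
- An equilibration window at or beyond the trajectory end yields an empty
  mask with a warning; the pipeline turns it into an error.
- An empty pure leaflet (APL), a lipid without phosphorus (leaflets), a
  donor without a bonded hydrogen, zero means in an enrichment ratio, and
  empty cluster membership all raise typed errors.

## Problem sizes

Default test problem sizes are chosen for seconds-scale feedback: the
shared fixture uses 200 frames × 3 peptides on the full 218-lipid bilayer;
the statistical-recovery fixture uses 10,000 frames (30,000 conformers),
which puts 4–5 standard errors between every recovered quantity and its
acceptance band. Examples use 100–800 frames.
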