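# Methods

This note documents the models, estimators, parameter choices and known
limitations of hydrascore, in the order of the pipeline.

## Atom typing and density channels

Heavy atoms are assigned one of 34 frozen atom types (16 protein, 18
ligand; `hydrascore.atom_types`, vocabulary version 1.0). Carbon splits by
ring membership ("aromatic") and by whether any neighbor is a heteroatom
("polar"); N and O split by donor/acceptor status; ligand halogens are
per-element; metals and anything outside the table fall into one generic
bucket per role (with a warning, never silently dropped). Donor/acceptor
status uses explicit hydrogens when present; otherwise implicit hydrogens
are inferred from heavy-atom valence, amide nitrogens are donors but not
acceptors, and terminal oxygens on carbons that also bind N/O are treated
as carbonyl-like acceptors. For proteins read from PDB (no bond block),
bonds are inferred from covalent radii (cutoff r₁+r₂+0.45 Å). These rules
are deterministic and order-independent but deliberately simple: charged
residue states, tautomers and aromaticity perception beyond ring
membership are out of scope.

The density kernel is the piece-wise Gaussian/quadratic function with
support [0, 1.5R); R is the type's van der Waals radius (1.9 Å C, 1.8 Å N,
1.7 Å O, ...). Grids are cell-centered: extent 24 Å at 0.5 Å spacing gives
exactly 48³ voxels with voxel centers at `center − extent/2 + (k+½)·s`.
Cell-centering was chosen so the extent is exact; the alternative
node-centering would give 49 points. Overlapping same-type atoms sum
(preserves mass additivity). Augmentation applies one uniform SO(3)
rotation plus a translation uniform in the 2 Å ball, rigidly to protein,
pose and (via the returned transform) water coordinates; images are
re-rendered from transformed coordinates rather than interpolated.

## Hydration analysis

Occupancy: each water oxygen visits exactly one voxel per frame; the voxel
value is the visit count normalized by `n_frames × bulk_occupancy`, with
`bulk_occupancy = 0.0334 waters/Å³ × voxel volume`. The count identity
`Σ ratio × bulk_occupancy × n_frames = total in-grid visits` holds exactly.
Voxels strictly above 2× bulk are pseudo-hydration sites; contributors are
all (water, frame) observations within a closed 1 Å ball of the voxel
center.

Enthalpy is the contributor mean minus a configurable bulk energy
(default −9.5 kcal/mol in the file-based tools; the synthetic study
conditions use −10). The entropy term is a translational-only estimator:
−TΔS = T·k_B·KL(q‖uniform) with T = 300 K, k_B = 0.0019872 kcal/mol/K, and
q the empirical distribution over the 0.25 Å sub-bins of the site sphere
(uniform occupation → 0; a point mass → T·k_B·ln m). Rotational entropy is
not modeled; outputs should be read as lower bounds on −TΔS.

Hydration sites (as opposed to per-voxel pseudo-sites) come from greedy
quality-threshold clustering: repeatedly take the occupancy argmax above
2×, claim a 1 Å-radius site, and remove voxels within 2 Å, giving centers
pairwise ≥ 2 Å apart.

Network channels are tanh-scaled into [0, 1): occupancy as tanh(ratio/2)
(bulk-ratio 2 maps to tanh(1)); enthalpy split into |ΔH|-negative and
ΔH-positive channels with scale 2 kcal/mol; the entropy term with scale
1 kcal/mol. The occupancy convention (a bulk ratio, not a probability) and
all scales are configuration.

The overlap coefficient requires non-negative grids (it normalizes each to
a distribution); signed grids must be pre-transformed (abs or sign-split),
and zero-total grids are rejected.

## Probe channels

Electrostatic hot spots are found by sweeping unit ±probes over the grid
with a clamped Coulomb energy (332.06·q/max(r, 0.5 Å) kcal/mol, pluggable
charge model). Extrema are strict 26-neighborhood minima that are
favorable (negative) with magnitude ≥ τ = 5 kcal/mol; the favorability
condition is ours — without it, an all-unfavorable field would report
spurious far-corner minima. Each extremum becomes a Gaussian of amplitude
1 and width σ = σ₀(0.5 + tanh(m/E₀)) (σ₀ = 1 Å, E₀ = 10 kcal/mol) in one
of four channels (probe sign × protein/ligand target). The width law is a
smooth monotone choice; only the magnitude dependency itself is
principled.

## Pose classifier

`PoseScoringCNN`: input C×D³ → three [3³ conv (stride 1, pad 1) + ReLU +
2³ max-pool] blocks → fully connected → two class logits (softmax in the
loss) plus an optional contact-score logit (sigmoid). Implemented directly
on NumPy arrays with explicit forward/backward passes, which keeps
training bit-reproducible per seed and gives the relevance module exact
access to weights, pre-activations and pooling argmaxes. D must be
divisible by 8.

Training: SGD with momentum 0.9, batch 16, learning rate 0.01, loss
weights λ_cls = λ_cms = 1, pseudo-Huber δ = 1. Training-time augmentation
rotates the input images on the grid (exact transposition/flip, all
channels together so protein, ligand and water stay co-registered). The
default group is the two-fold rotation about the grid z axis applied with
probability ½ — the symmetry the synthetic binding sites actually have,
and the invariance that stops a small network from memorizing which side
of a symmetric pocket a training system's native pose occupies (the same
role flips play for natural images). The full 24-element octahedral group
plus voxel shifts is available (`augment="octahedral"`), but demands more
invariance than the desk-size network can absorb in its 2000 iterations;
coordinate-space augmentation with continuous rotations
(`voxelize.augment`) re-renders images instead of transforming them. The
desk profile (default) uses filters (8, 16, 32) and 2000 iterations; the
full-scale profile
(32, 64, 128) / 40000 iterations exists behind
`PoseScoringCNN.from_profile("full")` but is not exercised by the test
suite. The contact-score head incurs loss on a pose whose true CMS is
below the 0.44 cutoff only when the prediction exceeds that cutoff:
non-overlapping poses carry no information about contact quality. The CMS
term is a second output head rather than a reshaped classification target;
the two-headed design keeps the classification probability calibrated
independently of the regression.

Ranking sorts poses by descending native probability with lexicographic
pose-id tie-breaks; top-N success is the fraction of systems with a
native-labeled pose in the first N ranks.

## Relevance propagation

Deep-Taylor z⁺ rule, starting from the native-class softmax output (the
pre-softmax logit is available behind a flag). Linear and convolutional
layers redistribute by positive weight×activation shares; nodes with
negative pre-activation pass on nothing; max pooling routes winner-takes-
all with equal tie splits; ReLU is transparent. Degenerate columns
(Σz⁺ = 0 under positive relevance) drop their relevance and are counted in
the output. Conservation holds exactly on bias-free networks whose start
node has non-negative pre-activation; with biases the rule loses relevance
by design, so conservation checks use zero-bias networks.

Aggregation: an atom receives, per voxel, its own kernel's share of its
channel's density times the voxel relevance. Water-channel voxels are
classified geometrically — replaced (≤ 2 Å from a ligand heavy atom),
interface-mediating (≤ 3.5 Å from both a ligand heavy atom and a protein
N/O/S), first-shell (≤ 4.5 Å from the ligand), other. The cutoffs are one
reasonable operationalization of those qualitative categories and are
configurable.

## Pose metrics

RMSD is computed in the shared docking frame (no Kabsch superposition;
poses and references already sit in the receptor frame — a `superpose`
variant is deliberately absent from the defaults), minimized over
element-preserving bond-graph automorphisms (NetworkX VF2, capped at
10,000 with identity fallback). The modified RMSD decomposes the ligand
into rigid fragments (cut acyclic single bonds between non-terminal heavy
atoms), computes each fragment's Shrake–Rupley SASA (960-point Fibonacci
sphere, probe 1.4 Å) in the bound protein context and for the unbound
ligand, and drops fragments with ratio > 0.25. Exposure is decided on the
reference pose, so the retained atom subset is identical across a pose
set; if everything is exposed it falls back to the standard RMSD with a
warning. CMS is the Tanimoto of protein–ligand heavy-atom contact sets at
4.5 Å, defined as 1 when both sets are empty. Native means RMSD strictly
below 2 Å.

Fold splitting links systems with sequence distance < 0.5 or ligand
similarity > 0.9, takes single-linkage groups, and assigns them largest-
first to the currently smallest fold (ties → lowest index); linked pairs
therefore never cross folds, and imbalance beyond ±1 is warned about.

## Synthetic study conditions

The generator emulates exactly what the pipeline consumes, not physics:
pockets are ~32 typed pseudo-atoms on a spherical shell, built
C2-symmetric about the z axis (the HIV-protease-like two-fold ambiguity);
ligands are 6–20-atom self-avoiding walks with 1.5 Å bonds placed 3.5 Å
off-axis with a guaranteed 2.8–3.5 Å polar contact. Decoys are rigid
perturbations whose RMSD is constructed exactly (centroid rotation plus
orthogonal translation), stratified so ≥ 1 pose is native-like and ≥ n/2
are clear decoys. Water trajectories plant hotspots (occupancy fraction 1,
positional σ 0.3 Å, energy −12 ± 0.5 kcal/mol) over uniform bulk at
0.0334 Å⁻³ with energy −10 ± 0.5, excluding the protein's 2 Å envelope and
a 2 Å hard core around each hotspot.

With hydration-dependent labels, a pose is native iff a ligand atom lies
within 2 Å of the hotspot, and the pose set contains the C2 images of all
native-like poses; each system is then flipped through the C2 axis with
probability ½, so which side is correct is itself random. The
class-conditional image distributions of the 34 geometry channels are
exchanged by the C2 rotation, so no geometry-only model can resolve the
side on held-out systems, while the occupancy channel disambiguates it
directly. This is the mechanism behind
the end-to-end check that the 35-channel model's held-out top-1 success
(≥ 0.80 expected, typically ≈ 1.0) exceeds the 34-channel model's
(≈ chance, ~0.3).

Study sizes: the ranking comparison uses 200 systems × 10 poses (150
train / 50 test), desk profile, three seeds; hydration recovery uses 500
frames (control: 1000) on a 24³ grid at 0.5 Å. These sizes give stable
statistics (enthalpy standard error ≈ 0.02 kcal/mol; binomial false-
positive tail ≈ 3% against a 5% bound) while staying desk-scale.

What passing these tests does **not** show: performance on real docked
poses, transferability across chemotypes, or the value of the
thermodynamic channels on real MD output — the toy pockets have no
conformational strain, no partial charges unless supplied, and their water
structure is planted rather than emergent.

## Numerical choices

float32 for training (float64 for relevance and gradient checks);
probabilities clamped at 1e-7 in the log loss; He/Xavier initialization
from a per-seed generator; pooling assumes even spatial dims; the RMSD
construction in the decoy generator is exact to ~1e-15, asserted to 1e-6.
Determinism contract: same seed → bit-identical synthetic data manifests
and training loss traces reproducible to 1e-5 relative.

## Known limitations

- No rotational water entropy; the translational estimator's sub-binning
  (0.25 Å) biases −TΔS down for very tight sites.
- Atom typing approximates donor/acceptor chemistry; rare types
  (protein halogens, metals) share generic buckets.
- The Coulomb probe model ignores anisotropy unless emulated upstream via
  off-center virtual charges through the pluggable charge model.
- The network is intentionally small; the full-scale profile is untested
  at scale here.
- MOL2 support covers MOLECULE/ATOM/BOND records only; mmCIF is absent.
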