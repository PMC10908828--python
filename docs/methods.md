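# Methods

`chapdyn` implements the quantitative analysis layer used in structural
studies of chaperone-client machines: a dimeric HSP90-type chaperone whose
two protomers enclose an interfacial ("luminal") cavity through which an
unfolded client segment threads, with a kinase-specific cochaperone
(CDC37-type) bridging client and chaperone. All stages operate on plain-text
inputs — PDB structures, multi-model PDB or whitespace frame-block
trajectories, and a per-atom parameter TSV — and none of them integrate
equations of motion; the package analyses trajectories, it does not
produce them.

## Residue-pair interaction decomposition

For two disjoint atom groups (e.g. the chaperone walls and the client
peptide), every atom pair contributes

- Coulomb: `E = k_e q_i q_j / (eps_in * r_ij)` with
  `k_e = 332.0637 kcal*A/(mol*e^2)`,
- Lennard-Jones 12-6: `E = 4 eps_ij [(sigma_ij/r)^12 - (sigma_ij/r)^6]`
  with Lorentz-Berthelot mixing (arithmetic sigma, geometric epsilon).

1-2 and 1-3 bonded pairs are excluded; 1-4 pairs are scaled by 1/1.2
(electrostatics) and 1/2 (LJ), the convention of the Amber fixed-charge
force-field family whose parameter tables the package reads. Entries are
summed per residue pair and averaged over frames.

Two deliberate conventions:

- **No distance cutoff.** This is a post-hoc decomposition of snapshots,
  not a dynamics engine; the direct sum makes the conservation property
  exact (the sum of all residue-pair entries equals the directly computed
  inter-group energy) and is the standard convention of per-residue
  decomposition tools.
- **Gas-phase electrostatics** (`eps_in = 1`) for decomposition entries.
  Published strongest-pair coulombic values for this system class are of
  gas-phase magnitude; whether any solvent screening was applied upstream
  is not derivable from the inputs, so none is applied here.

Replica statistics follow the convention of multi-replica MD studies:
per-replica means, the cross-replica mean (mean of replica means), the SD
of the replica means (ddof = 1), and SEM = SD/sqrt(R). With one replica,
SD/SEM are reported missing rather than zero.

Negative energies are favorable. Heatmap export clamps a *rendering copy*
to ±clip (default 1.0 kcal/mol, the usual display threshold); the TSV
always keeps full precision.

## MM-GBSA

Binding free energies use the single-trajectory protocol: receptor and
ligand coordinates are sub-selections of the complex frames, so internal
bonded terms cancel and

`dG = < dE_vdw + dE_coul + dG_GB + dG_np >`.

- **Generalized Born.** Effective radii follow the
  Hawkins-Cramer-Truhlar pairwise descreening integral with screened
  neighbour radii `S_j * (rho_j - offset)`, rescaled through the OBC tanh
  correction `R_i^-1 = rho_t_i^-1 - rho_i^-1 tanh(alpha psi - beta psi^2 +
  gamma psi^3)` with alpha = 1.0, beta = 0.8, gamma = 4.85 (the OBC-II
  coefficient set) and dielectric offset 0.09 A. The energy is the full
  double sum over `f_GB = sqrt(r^2 + R_i R_j exp(-r^2/(4 R_i R_j)))`
  including self terms; for one ion it reduces to the Born expression,
  which the test suite checks to 1e-6 relative error. Solvent dielectric
  78.5, interior 1.0, salt 0 (no Debye screening term).
- **Nonpolar term.** `gamma_np * SASA + b` per species with
  gamma_np = 0.0072 kcal/mol/A^2 and b = 0 (both configurable). SASA is
  Shrake-Rupley with a deterministic golden-spiral point set (default 960
  points, probe 1.4 A); atomic radii default to LJ R_min/2.
- **Omissions (by design).** No Poisson-Boltzmann option, no normal-mode
  entropy, no separate-trajectory protocol: the studies this package
  serves simulate complexes only and report MM-GBSA energies without
  entropy corrections.

Per-residue decomposition splits every pairwise gas-phase and GB cross
term half to each partner residue; GB self terms and per-atom SASA
differences go to their own residue. Residue contributions therefore sum
exactly to the per-frame total (tested to 1e-6 kcal/mol).

Note on dense pseudo-atom fixtures: the HCT pairwise sum assumes weakly
overlapping neighbour spheres. In the synthetic wall lattices neighbours
overlap heavily, so buried wall atoms saturate at the OBC limit
`R -> rho rho_t / offset`. This is the correct behaviour of the stated
equations; it simply means synthetic-wall GB energies should be read as
model quantities, not protein-like values.

## RMSF, B-factors, and essential dynamics

Frames are superposed by least-squares (Kabsch) fitting, either to the
first frame or iteratively to the running mean (default, at most 10
rounds or until the mean shifts < 1e-6 A). RMSF is taken about the
post-fit mean; `B = (8 pi^2 / 3) RMSF^2`.

Cross-state comparison requires a shared scale. The normalization here is
**joint-max**: all profiles are divided by the pooled maximum raw B and
multiplied by 100. This preserves within-profile ratios exactly and keeps
between-state magnitude ordering, which is what side-by-side "colored by
normalized B" figures compare. (Published figure captions state only that
profiles were normalized; the joint-max rule is this package's declared
choice and is not asserted against any published value.)

PCA operates on mean-centred C-alpha coordinates, mass-unweighted, with
population (1/F) covariance normalization so the eigenvalues partition the
total coordinate variance exactly (Parseval check in the tests). The SVD
route keeps rank-deficient trajectories well-defined; requesting more
modes than the rank truncates with a warning. Mode animations interpolate
`mean ± amplitude * sqrt(lambda_k)` along eigenvector k.

## Cavity volumetrics

The luminal cavity is measured on a voxel grid (default h = 0.5 A) with a
two-grid scheme chosen for leak-robustness:

1. *Exterior sealing*: flood fill (6-connectivity) from the grid boundary
   over free voxels of a grid whose atom radii are inflated by the probe
   (1.4 A). Sub-probe gaps between wall atoms cannot leak solvent.
2. *Volume*: flood fill from a seed point (default: client-segment
   centroid, snapped up to 3 A to the nearest free voxel) over free
   voxels of the *uninflated* grid, intersected with non-exterior voxels.

Walls are the two protomer chains only; client and cochaperone are
excluded from the walls so the client's own volume does not carve the
cavity. Occupancy is the fraction of cavity voxels covered by the client
atoms' vdW spheres (no inflation). Volume error is O(h) on analytic
phantoms; the voxel-center membership rule gives a half-voxel bias that
the phantom tests bound at ±5%.

If the seed's probe-inflated free region reaches the grid boundary the
cavity is declared open at that probe radius and an error suggests a
larger probe, rather than returning a silently unbounded volume.

## Alignment-guided comparison and peptide descriptors

Structure comparison is sequence-driven: global Needleman-Wunsch with
BLOSUM62 and affine gaps (open 10, extend 0.5 — common defaults, declared
since upstream publications are silent), then Kabsch superposition of the
matched C-alphas. Identity uses aligned columns between the first and
last doubly-occupied column (terminal overhangs excluded); the
shorter-sequence denominator is reported alongside. Similarity counts
pairs scoring > 0 in BLOSUM62, with identical pairs always similar (X is
scored 0 against everything). Reflections are excluded from the rotation
(det +1 asserted on every call). Published RMSD values for this system
class were produced with secondary-structure matching; the
alignment-guided route here is fully specifiable, and comparisons against
those values should carry a ±0.3 A method tolerance.

Peptide descriptors: GRAVY (mean Kyte-Doolittle), percent hydrophobic
residues (A,V,L,I,M,F,W,C,P), and isoelectric point by bisection on the
Henderson-Hasselbalch net charge with the EMBOSS pKa set (C 8.5, D 3.9,
E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1; termini 8.6/3.6). Z(pH) is strictly
decreasing, so the root is unique; the interval is bisected below 1e-8 pH.

## Synthetic data: what it emulates, and what it does not

The generator produces every fixture the pipeline needs, deterministically
under a master seed (replica r uses seed + r):

- **Toy complexes**: chains of single-pseudo-atom residues with one LJ
  class (sigma 3.4 A, epsilon 0.1 kcal/mol, Born radius 1.7 A, screen
  0.8) and simple charge patterns, so every oracle stays hand-computable
  (e.g. a +1/-1 pair at 3.320637 A gives exactly -100 kcal/mol Coulomb).
- **Gaussian trajectories**: frames displaced along orthonormalized
  planted 3N modes with normal amplitudes plus isotropic noise — exactly
  the statistical model under which RMSF and PCA recovery have closed
  forms.
- **Cavity phantoms**: box shells of pseudo-atoms whose innermost lattice
  plane sits exactly at `void_half + r_vdw`, so the nominal void volume is
  the analytic truth (up to the inter-atom scallop, O(s^2/r), kept below
  the test tolerances by the 0.6 A default lattice spacing).
- **Threaded-dimer scene**: two C2-symmetric protomer walls sealing a
  12 x 8 x 8 A channel, a 9-residue client threaded along the axis, one
  planted strongest coulombic pair (a +1 client residue against a -1 wall
  atom) and one planted strongest vdW pair (a high-epsilon wall atom over
  client residue 7). Ground truths: pair identities, nominal cavity
  volume with a 12% voxelization/scallop allowance, client volume from an
  exact 1D union-of-spheres integral, occupancy with a 25% relative
  allowance (the ratio compounds both grid errors), protomer RMSD 0 by
  construction, favorable binding, and a *gas-phase* interaction that is
  strictly more favorable than the neutral control scene. The total
  MM-GBSA dG is deliberately not claimed monotone in the planted
  contacts: the buried salt bridge's desolvation penalty exceeds its
  Coulomb gain under the implemented GB model, a physically expected
  outcome for charge pairs buried in a low-dielectric channel.

What the synthetic data does **not** emulate: real force-field chemistry
(multiple atom types, hydrogens, bonded terms), solvent, anharmonic or
correlated protein motions, and realistic packing. Passing tests
demonstrate that the implemented estimators recover planted ground truths
under their own statistical assumptions — they do not validate biological
conclusions about any particular protein system.

## Problem sizes and defaults

The test and acceptance workloads are sized for a single CPU: Gaussian
recovery at 10^4 frames x 8-10 atoms, PCA recovery at 5 x 10^3 frames,
phantoms of ~8 x 10^3 wall atoms at h = 0.5 A, and a threaded-dimer scene
of ~1.9 x 10^3 atoms with 20 frames in 2 replicas, with MM-GBSA evaluated
on 2 frames per replica and 240 sphere points in the pipeline
configuration (960 elsewhere). These sizes are the package's declared
study conditions for its self-checks; all are configurable.

## Known limitations

- The GB implementation is all-pairs O(N^2) per frame and the SASA
  implementation O(N * points * neighbours); both are intended for
  analysis-scale systems (10^3-10^4 atoms), not large solvated boxes.
- Only legacy fixed-column PDB and the plain frames dialect are read; no
  mmCIF or binary trajectory formats.
- Altloc handling keeps the highest-occupancy conformer; insertion codes
  are preserved as residue-key suffixes; hydrogens are used only if
  present and parameterized (no builder).
- The cavity stage analyses single structures, not trajectories, and
  traces no channels or tunnels.
- Sequence alignment is pairwise global only; no multiple alignment, no
  secondary-structure assignment.
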