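# Methods

## The model

A peripheral membrane protein bound to a planar bilayer is described by a
small set of discrete **binding modes**.  Each mode is a stable rigid-body
orientation characterized by

* a **contact set** — the residues whose beads/atoms come within the
  contact cutoff of lipid particles in a threshold fraction of frames;
* an **altitude** — the vertical distance between the membrane surface and
  a reference point on the protein;
* an equilibrium **occupancy**, from which relative mode energies follow
  by the Boltzmann relation `ΔE_ij = −k_B T ln(p_j/p_i)`.

The membrane surface (altitude zero) is the mean z of the phosphorus
particles of the facing leaflet.  The membrane normal is the z axis and
all internal units are nm; PDB ångström values are converted at the I/O
boundary.

### Contacts

A contact is a protein–lipid particle pair at centre–centre distance
**strictly below 0.6 nm**.  The strict inequality is part of the
definition, and the k-d-tree-accelerated search is required (and tested)
to agree exactly with an all-pairs computation, including pairs at
exactly the cutoff.  Solvent is never a contact partner; for atomistic
systems hydrogens are excluded by default (`heavy_only`) so the statistic
counts heavy-atom contacts.  Minimum-image distances are used when a
periodic box is present and requested; whether the original contact
analyses wrapped boundaries is not documented, so periodicity is an
explicit flag rather than a default.

Two intensity notions are both reported, since it is ambiguous which one
"contact intensity" denotes: the raw pair count per frame and the number
of distinct residues in contact per frame (a residue counts once per
frame no matter how many of its particles touch).

### Mode classification

Each trajectory is summarised by a **fingerprint**: the per-residue
contact fraction over the post-landing window (landing frame + a
persistence margin; the approach segment would dilute the pattern).
Fingerprints are merged by single-linkage agglomeration whenever their
similarity reaches a threshold.  The default similarity is the Jaccard
index of the stable supports (fraction ≥ 0.5) with merge threshold 0.5 —
classification by shared residue sets, which is how the orientations are
distinguished in practice; cosine similarity on the raw vectors is the
alternative.  Mode labels are ordered by descending mean contact
intensity (mode 1 = deepest, most contacts), ties broken by lower mean
altitude.

Two mode regions are **overlapping** when they share residues,
**neighboring** when any cross-pair of residue centres is within 0.8 nm
(a Cα–Cα contact-scale distance), else **disjoint**.  The allowed
transition path between the deepest and shallowest modes is the Dijkstra
path over non-disjoint pairs weighted by uphill energy only — the
reasoning concerns the cost of switching, not equilibrium sums.

### Altitude

`reference="top"` (default) measures from the maximum protruding protein
particle, because the AFM observable that simulation altitudes are
compared against is a top-surface height; `reference="com"` (centre of
geometry) is provided because an "average height" reading is equally
defensible.  Which protein point defines the simulation altitude is the
single largest numeric ambiguity when matching modalities; it is surfaced
as configuration, not resolved.  The leaflet split for the interface uses
the midpoint of the minimum and maximum phosphorus z — robust for flat
patches, not for vesicles.

### AFM deconvolution

The background plane is the densest 0.05 nm histogram bin of the image,
refined by the median of pixels within ±0.1 nm.  Globules are connected
regions above background + 0.5 nm, one measurement per local maximum with
4 nm minimum separation (taller peak wins); the per-particle statistic is
the **peak** altitude over background, matching the top-surface altitude
convention.  The pooled altitudes are decomposed by a K-component 1-D
Gaussian mixture fitted with EM on the raw samples — best of n seeded
restarts (quantile-initialized means, perturbed), convergence at
log-likelihood gain < 1e-8, per-iteration monotonicity asserted,
degenerate components (collapsing sd) abort the restart.  EM avoids the
bin-width sensitivity of histogram least squares; a histogram backend is
kept and must agree with EM on planted fixtures.  K is always caller
-chosen (K = 3 for this system); a BIC sweep exists but is advisory only.

### Energetics

`k_B = 0.0083144626 kJ/(mol·K)`; energies are reported in kJ/mol and kT.
The default temperature is 295 K (the simulation temperature; whether the
experimental diagram used 295 or ambient 298 K is unstated, so it is
configurable).  The most populated mode defines the zero of energy.

### Backmapping

Atomistic poses are recovered from coarse-grained frames by fitting the
reference Cα set onto the BB beads (paired by residue index, never
spatially) with an SVD Kabsch solver; the smallest singular vector is
sign-corrected so a proper rotation (det +1) is always returned.  The
whole protein is placed as a single rigid body — appropriate because the
internal structure changes little during coarse-grained runs; side-chain
rebuilding and minimization are out of scope.

## Synthetic data: what it emulates and what it does not

The generators plant ground truth with the characteristic values of the
emulated system so that every analysis is a parameter-recovery exercise:

* **Protein**: 134 one-bead residues in a self-avoiding globule of
  ~2.9 nm diameter (minimum separation 0.3 nm).  The default mode-1
  contact set is the 17-residue interfacial binding surface
  {1,2,3,4,14,23,24,55,78,81,82,85,86,91,92,110,134}; mode 2 is a
  10-residue set including Trp128 and sharing residue 134 with mode 1;
  mode 3 is a 6-residue β-loop set from 105–115 sharing residue 112 with
  mode 2 and nothing with mode 1.  The globule places the mode-1 patch at
  the south pole and the mode-3 core at the north pole so the planted
  regions reproduce the observed geometry (1–2 and 2–3 adjacent, 1–3 on
  opposite faces).  This geometry is planted, not emergent.
* **Bilayer**: 15 × 15 lipids per leaflet on a 0.8 nm lattice, one "P"
  bead per lipid at ±2.0 nm plus two tail beads; the upper-leaflet P mean
  defines the interface exactly when jitter is zero.
* **Trajectories**: rigid bound pose with contact residues anchored
  0.35 nm above distinct phosphorus beads (inside the cutoff), all other
  residues ≥ 1 nm above the plane (outside it), and a designated apex
  bead whose z is drawn per frame from N(planted altitude, planted sd) —
  the altitude distribution is therefore exactly Gaussian by
  construction.  Per-residue Gaussian jitter (default sd 0.05 nm,
  optionally per-residue) models mobility.  The first 10 % of frames are
  an approach from ≥ 1 nm above held ≥ 0.5 nm off the bound pose, so the
  first contact frame equals the planted landing frame.
* **AFM fields**: flat background at 0 plus isotropic Gaussian caps
  (lateral sd 1.5 nm, an idealized tip-convolved globule) whose peak
  heights are drawn from the three-component mixture; additive pixel
  noise, default sd 0.05 nm.  Bump centres are snapped to pixel centres
  so planted peak heights are exactly representable on the grid.
  Default mixture: means (1.74, 2.37, 2.90) nm, weights
  (0.430, 0.346, 0.224), sd 0.15 nm per component.  The component widths
  are not experimentally constrained; 0.15 nm is an arbitrary default and
  flagged as such.  The weights are computed at import by 1-D root
  finding from w₁ = 0.43 and the constraint ln(w₂/w₃) = 2 ln(w₁/w₂)
  (the two-fold switching-energy ratio), so that identity holds to
  machine precision.

What passing these tests shows: the estimators are unbiased and correctly
calibrated on data that satisfy the model's assumptions (rigid modes,
Gaussian altitudes, flat membrane, well-separated globules).  What they
do not show: robustness to membrane undulation and curvature, partial or
drifting AFM backgrounds, tip-shape artifacts, overlapping globules,
conformational change within a mode, or mode switching inside a single
trajectory — none of which the generators produce.

All generators are pure functions of their arguments including the seed
(NumPy PCG64); identical seeds give bit-identical output, and pipeline
reports are byte-identical for a fixed (config, seed).

## Numerical choices and problem sizes

* Landing-frame detection requires contacts persisting ≥ 5 frames
  (configurable); the fingerprint window starts at landing + persistence.
* RMSF superposes every frame onto the running-mean conformation with the
  Kabsch solver, refining the mean for 3 iterations.
* Mixture-recovery checks use 2000 samples (detection-based closure: 600
  globules over several fields of view, ~100 per field, matching a
  realistic per-image count); altitude-recovery checks use 500
  post-landing frames with sd 0.05 nm, giving a 3σ/√n recovery band of
  ~0.007 nm (asserted at 0.02 nm).
* EM location equivariance is asserted at 1e-6 nm: the shift identity is
  exact in exact arithmetic but not bitwise under floating point.
* The contact search recomputes candidate distances and filters with a
  strict `<` so tree pruning can never change the result.

## Known limitations

* The interface estimate ignores the membrane deformation under the
  protein footprint; altitudes over a locally dimpled membrane would be
  biased.
* Mode assignment assumes one mode per trajectory; a trajectory that
  switches modes mid-run would get a mixed fingerprint.
* The cluster analysis of protein conformations is deliberately reduced
  to the per-residue RMSF profile.
* Binary trajectory formats (XTC/DCD) are not read; desk-scale inputs
  are text (multi-model PDB, concatenated GRO, XYZ).
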