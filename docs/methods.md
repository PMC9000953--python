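# Methods

This note documents the models, numerical choices and synthetic study
conditions behind `abcaxis`, and what the tests do and do not establish.

## The conformational axis

**Model.** A structure ensemble is represented as an M × 3N matrix X: M
structures, each contributing the flattened CA coordinates of the same N
"stretch" residues (ordered residue intervals of 7–21 residues chosen at
structurally equivalent positions), all expressed in one reference frame.
Essential dynamics is PCA of the Cartesian coordinates: eigendecomposition
of the population covariance `C = (1/M) XᶜᵀXᶜ` of the mean-centred matrix.
Eigenvectors are collective deformation modes (unit 3N-vectors), eigenvalues
their mean squared amplitudes (Å²), and the projection of a structure on the
leading eigenvector is its coordinate on the one-dimensional conformational
axis.  For the transporters this package targets, AtAtm3's published stretch
selection (140–160, 225–245, 255–275, 322–342, 362–382, 423–443, 504–513,
517–524, 618–632, 681–688; 167 residues) and NaAtm1's are built in;
homodimers contribute one half-transporter, heterodimers both halves.

**Frame alignment.** Each member is rigidly superposed onto a designated
outward-facing reference using a subset of positions (conventionally the
TM3+TM6 stretches, which move least over the transport cycle) and the whole
coordinate set is carried along by that transform.  This removes rigid-body
motion without letting the mobile domains dominate the frame fit.

**Numerical choices.**

* Covariance is normalized by M (population form), the essential-dynamics
  convention, so eigenvalues are reproducible; no mass weighting (CA-only,
  uniform weights).
* The decomposition runs through the economy SVD of Xᶜ rather than forming
  the 3N × 3N covariance; eigenvalues are s²/M.  At most M−1 are nonzero.
  The explicit covariance eigendecomposition is kept as an independent
  cross-check in the tests (agreement to 1e-9 relative).
* Eigenvector signs: the first coordinate above 1e-12 in magnitude is made
  positive; when an outward-facing reference structure is named, component 1
  is flipped if needed so that structure projects to the positive (outward)
  extreme.  Degenerate eigenvalues keep the stable decomposition order.
* Projections are reported in Å along a unit mode (the raw dot product).
  Published axis plots for this transporter family label component-1 values
  in Å² with inward-facing structures clustering near −100 and outward near
  0; because that unit labeling is ambiguous, the package emits raw
  projections and treats any fixed scaling as presentation.  The default
  classification bands are anchored on the published clusters
  (inward ≈ −100, occluded/closed ≈ −25, outward just below 0), with edges
  at midpoints between band centers, half-open intervals, and ties assigned
  to the more inward band; band centers are configuration, and analyses on
  synthetic ensembles derive bands from the planted state means.

**Alternative metrics.** Distances between specific residue pairs (e.g. the
NBD–NBD separation) are computed per structure and correlated with the axis
by Pearson's r.  Distances that close as the transporter opens outward
anti-correlate with component 1; which pairs to use is configuration.

## Superposition and RMSD

Rigid superposition is the Kabsch SVD solution on explicit CA
correspondences, with the reflection corrected so det(R) = +1; inputs of
fewer than 3 pairs or collinear clouds are rejected as degenerate.
Same-protein comparisons pair residues by author numbering; cross-species
comparisons require explicit stretch-to-stretch maps — no structural
matching heuristic is implemented, which is the main deliberate difference
from the secondary-structure-matching tools used interactively in the
field.  Printed same-protein RMSDs are therefore expected to reproduce only
within about ±0.3 Å, absorbing the residue-pairing difference.  Scope
presets: full dimer, single chain ("half"), and NBD-only (residues
C-terminal of TM6; ≥ 461 for AtAtm3, configurable).

## Cavity volume and SASA

**Cavity (grid flood fill).** Grid points (default spacing 0.5 Å) within
`r_vdw + probe` of any heavy atom are occupied; exterior space is located by
6-connected flood fill from the padded bounding-box boundary; enclosed empty
points are cavity, volume = count × spacing³.  The default probe is 2.5 Å
(substrate-cavity scale); SASA uses the 1.4 Å water probe.  Two bounding
policies: `interior-only` counts fully enclosed cavities (adequate for the
closed conformation, whose cavity is sealed) and `capped-hull` additionally
counts empty points inside the convex hull of the CA atoms, treating the
hull as a cap so that cavities open to one membrane face register.  This is
a declared functional stand-in for alpha-shape pocket detection: enclosed
volumes agree with analytic solids to better than 10% at 0.4 Å spacing, but
open-pocket volumes depend on the capping geometry and support ordering
comparisons only, not equalities.

**SASA (Shrake–Rupley).** Each atom is inflated by the probe and sampled
with a deterministic golden-spiral point set (default 960 points); the
exposed fraction of points times the inflated-sphere area gives the per-atom
area, summed into per-residue areas.  Van der Waals radii default to
C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20, fallback 1.70 Å; hydrogens
are ignored, and ligands/lipids/waters are excluded from the surface unless
requested.  Quadrature error on analytic cases (isolated and pairwise
overlapping spheres) is below 1%; because the point set is fixed in the lab
frame, rigid-transform invariance also holds to quadrature error, not to
machine precision.  Binding-pocket ASA sums per-residue areas over a residue
list expanded across both protomers; the built-in default list is the
conserved glutathione-pocket set (317, 324, 328, 387, 390, 433, 437, 441).
Published pocket-ASA sums used a richer (unpublished) residue list, so
pocket-ASA comparisons are ordering checks.

## Transmembrane cysteine census

Alignment columns are mapped to reference residue numbers (strictly
increasing over non-gap reference columns from a configurable offset).
Cysteines are counted per reference position within six declared TM spans;
the overall frequency is 100 × (Cys cells)/(non-gap cells) over TM columns —
the gap-free denominator is a documented choice.  The reference row is
excluded by default (the census describes the homologs).  TM6 is the
published 416–460; TM1–TM5 default to approximations (135–165, 200–230,
255–290, 300–330, 380–410) placed so the family's reported TM cysteine
positions (149, 215, 290, 307, 405) fall within their stated helices — exact
boundaries for TM1–TM5 are not published and the census itself is exact for
any spans supplied.  The conservation profile is 1 − H/log 20 per column
(Shannon entropy of non-gap residue frequencies): a monotone, qualitative
stand-in for phylogenetically weighted conservation scoring.

## ATPase kinetics

`v = V_max·S/(K_m + S)` is fit per condition by unweighted nonlinear least
squares (replicates enter as individual points; no basal-rate subtraction).
Initialization is data-driven and reproducible: V_max⁰ = max(v), K_m⁰ = S at
half-max by interpolation of per-concentration means.  Rates are normalized
by max|v| inside the optimizer so the fit is exactly equivariant under
rescaling of v; standard errors come from the scaled covariance.  Fits
require ≥ 4 distinct concentrations and reject non-positive optima.

## Synthetic study conditions

The generators are pure functions of their spec including the seed (one
`numpy.random.default_rng` per call).  Defaults pin them to the study this
package reimplements:

* **Ensemble**: M = 80 members (the size of the published type IV
  transporter survey) built on an ideal 6 × 21 CA helix bundle (N = 126;
  1.5 Å rise, 100°/residue, 2.3 Å helix radius, ring radius 9 Å), deformed
  along three orthonormal random modes with SDs 3.0/1.5/1.0 Å plus 0.0775 Å
  isotropic coordinate noise.  By the closed form
  `σ₁²/(Σσ² + 3N·σ_n²)` the leading mode carries 62% of the expected
  variance — the share the published ensemble attributes to component 1.
  A built-in "NBD-separation" mode translates two residue groups along
  their center line to emulate the inward↔outward motion for classification
  and anti-correlation tests; two-state ensembles draw bimodal mode
  coefficients (two separated clusters), since that is what distinct
  conformational states look like.
* **Alignment**: 410 homologs over a 700-residue cysteine-free reference;
  substitutions (rate 0.3) never introduce cysteine, so cysteine placement
  is exactly the planted carrier profile: fractions at positions
  149/215/290/307/405 plus two rare sites, giving an expected TM frequency
  of 0.40% and zero cysteines in TM6 under the default spans.
* **Kinetics**: the six published conditions (DDM/nanodisc × no substrate /
  GSSG 2.5 mM / GSH 10 mM) with their printed V_max (104/117/154 and
  7.7/32/39 nmol/min/mg) and K_m (0.16 / 0.08 mM), a 7-point MgATP grid
  from 0.025 to 2 mM, triplicates, and 5% multiplicative noise (typical
  colorimetric-assay repeatability).
* **Cavity shell**: wall atoms on a Fibonacci sphere of radius
  `free_radius + r_vdw`, dense enough that the largest hole circumradius
  stays well under the probe reach (an undersized wall raises an enclosure
  error); the enclosed probe-free volume is analytically
  (4/3)π(free_radius − probe)³.

**What the synthetic data does not emulate**: real transporter ensembles
have anharmonic, state-dependent deformations, heterogeneous resolution and
modelling error, correlated substitution patterns and phylogenetic
structure, and kinetics with outliers and systematic (not just Gaussian
multiplicative) error.  Passing the synthetic suites therefore demonstrates
the correctness of the numerics and bookkeeping under the stated generative
models, not agreement with any particular experimental dataset.  The direct
comparisons against deposited AtAtm3 coordinates (printed RMSDs, the
cross-protomer CA distances, the closed-state cavity volume) run only when
those coordinate files have been fetched into `data/structures/`; they are
not bundled.

## Problem sizes

Test and acceptance runs use M = 80–500 ensemble members on the N = 126
bundle, 410-sequence alignments, 21-point kinetics datasets, 1000-replicate
fit-coverage simulations, and 0.4 Å cavity grids on shells of ~130 atoms —
sizes chosen so the full suite completes in seconds while leaving sampling
error comfortably inside the asserted tolerances.

## Known limitations

* No automatic structural matching: cross-species ensembles need explicit
  stretch maps, as published selections only exist for two transporters.
* Open-state cavity volumes depend on the capped-hull construction and are
  comparable only within one policy.
* The conservation score is not phylogenetically corrected; duplicated or
  closely related sequences inflate apparent conservation.
* Multi-model files use model 1 only; insertion-code residues are excluded
  from ranged selection.
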