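# abcaxis

Conformational-landscape analysis of type IV ABC transporters.

ABC exporters such as the mitochondrial Atm family move substrates across a
membrane by alternating access: the translocation cavity opens alternately to
the matrix (inward-facing) and the intermembrane space (outward-facing), via
occluded and closed intermediates, driven by ATP binding and hydrolysis at
the nucleotide-binding domains (NBDs).  Comparing the dozens of deposited
transporter structures requires a common coordinate for "how far along the
cycle" each one sits.  `abcaxis` builds that coordinate and the analyses that
surround it:

* **Conformational axis.** CA coordinates of a fixed set of residue
  stretches (7–21 residues each, spanning TMD and NBD) are extracted from
  every structure, superposed into a common reference frame, and stacked
  into an M × 3N matrix.  Essential-dynamics PCA — the eigendecomposition of
  the population covariance `C = (1/M) Xᶜᵀ Xᶜ` of the mean-centred matrix —
  yields collective deformation modes; the projection of each structure on
  the leading eigenvector `v₁` (its *component 1* value, `p₁ = (x − x̄)·v₁`)
  orders the ensemble from the most inward-open to the most outward-open
  conformation.
* **Superposition/RMSD.** Kabsch least-squares rigid superposition over
  explicit CA correspondences, with dimer / half-transporter / NBD-only
  scopes.
* **Cavity and surface profiling.** Probe-based enclosed cavity volume by
  grid flood fill (default probe 2.5 Å, sized for the central substrate
  cavity) and Shrake–Rupley solvent-accessible surface area (probe 1.4 Å),
  both functional stand-ins for the alpha-shape and Lee–Richards programs
  traditionally used.
* **Transmembrane cysteine census.** Per-position cysteine counts over a
  homolog alignment mapped to reference numbering, restricted to the six TM
  helices — relevant because disulfide substrates (GSSG) can form inhibitory
  mixed disulfides with cysteines in the translocation pathway — plus a
  normalized-entropy conservation profile.
* **ATPase kinetics.** Michaelis–Menten fits `v = V_max·S/(K_m + S)` of
  (S, v) rate data by nonlinear least squares, per solubilization/substrate
  condition.
* **Synthetic data.** Generators with known ground truth for every input:
  planted-mode coordinate ensembles, hollow cavity shells with analytic
  volumes, homolog alignments with controlled cysteine placement, and noisy
  kinetics — so every stage is testable against closed forms.

## Worked example

Generate a synthetic 80-structure ensemble at the study conditions and run
the axis pipeline:

```bash
$ abcaxis simulate ensemble --seed 17 --out ens
INFO abcaxis: wrote 80 conformers + manifest.tsv to ens
$ abcaxis axis build --manifest ens/manifest.tsv --out axis-out
INFO abcaxis: axis pipeline complete: 80 structures, component 1 carries 60.3% of the variance
```

`axis-out/summary.json` records the run:

```json
{
 "tool": "abcaxis 0.1.0",
 "n_structures": 80,
 "n_residues": 126,
 "component_1_variance_fraction": 0.6025827968552502
}
```

The generator plants three orthogonal deformation modes whose leading mode
carries 62% of the expected coordinate variance; the pipeline recovers a
component-1 share of 60.3% on this 80-member draw (sampling fluctuation at
M = 80).  `axis-out/projections.tsv` lists each structure's component-1
value, its state labels and its assigned axis band.

Fit synthetic ATPase data for the nanodisc basal condition:

```bash
$ abcaxis simulate kinetics --seed 17 --out kin
$ abcaxis mmfit --data kin/atpase.tsv --condition nanodisc:none
[
 {
  "condition": "nanodisc:none",
  "v_max": 7.490105837528599,
  "k_m": 0.07680810882761369,
  ...
 }
]
```

The generating truth for this condition is V_max = 7.7 nmol/min/mg and
K_m = 0.08 mM; the fit recovers 7.49 and 0.0768 from 21 noisy points
(7 MgATP concentrations in triplicate, 5% noise).

Other subcommands: `ingest`, `superpose`, `cavity`, `sasa`, `census`,
`simulate shell|msa|kinetics`.  See `abcaxis --help`.

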