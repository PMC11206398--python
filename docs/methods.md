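# Methods

This note records the models, conventions and numerical choices behind
`tkispec`, and what the synthetic validation does and does not establish.

## Conformer thermochemistry

Strain energy is defined against the ensemble's global-minimum conformer,
SE*ᵢ* = (*Eᵢ* − *E*₍min₎) × 627.509474 kcal/mol, using electronic energies
directly: no zero-point, thermal or entropic corrections are applied, since
the upstream data for this series are bare SCF totals. Energies are kept in
hartree internally and converted only at API boundaries — the series'
energies are bookkept as small offsets from large integer bases
(−933 … −3507 E_h), and converting early would discard precision.

Populations are degeneracy-weighted Boltzmann fractions,
*pᵢ* = *gᵢ* e^(−SEᵢ/RT) / Σ*ⱼ* *gⱼ* e^(−SEⱼ/RT), computed with a log-space
softmax so deep wells cannot underflow the normalization. Defaults:
T = 298.15 K ("room temperature" is not otherwise quantified in this
context) and *gᵢ* = 1 for every conformer — conformational degeneracy
matters in principle but no values are available, so it is an explicit
per-label override rather than a guess. Published population percentages
for this series are not exactly reproducible by this formula (the original
recipe — temperature, energy type, degeneracies — is not stated), so the
population machinery is validated by its closed-form and limiting
properties, not by matching printed percentages.

## Superposition and RMSD

Two alignment routes are exposed because the field uses both:

- **Plane anchoring** puts a structure in the canonical frame of three named
  quinazoline-core atoms (C1, C4, C10): first anchor at the origin, second
  on +x, anchor plane at z = 0. Comparing two structures anchored this way
  measures deviation *given* a fixed core orientation, which is how the
  crystal poses of this series are compared; flexible appendages (the two
  methoxy arms, the halogenated phenyl ring) cannot pull the fit.
- **Kabsch superposition** finds the least-squares optimal rigid motion over
  mapped atoms via the SVD of the centred covariance; when the unconstrained
  optimum is a reflection the proper-rotation branch is taken and flagged.

`crystal_vs_minimum_rmsd` defaults to plane anchoring whenever anchors are
configured, falling back to Kabsch otherwise; anchored RMSD is always ≥ the
Kabsch optimum, and both numbers are a function call apart. Anchor atoms
are always resolved through an explicit per-molecule atom map, never
inferred from element patterns. The default atom subset is heavy atoms:
hydrogen positions from electronic-structure optimizations are
conformation-noisy and the published atom set is unstated. Correctness is
established against a brute-force rotation-grid + local-refinement oracle
(1e−3 Å on small toys) and an independent library implementation.

## Spectra

Sticks are broadened in the **energy** domain: each transition contributes a
Gaussian centred at *E* = 1239.84/λ eV with area equal to its oscillator
strength, so integrated energy-domain intensity equals Σ*f* up to grid
truncation (verified to 1%). The default FWHM of 0.333 eV is a common
convolution width for excited-state sticks; the original broadening for
this series is unpublished, which is also why **λmax is read off the sticks,
not the broadened curve**: the principal band is the longest-wavelength
transition with *f* ≥ 0.5 (threshold configurable), with ties broken by
larger *f*, and a missing qualifying transition is a hard error rather than
a silent fallback. The default grid is 180–350 nm at 0.1 nm.

Δλmax = λ₍crystal₎ − λ₍cal₎; negative values are labelled blue shifts
(crystal band at shorter wavelength). Difference spectra are strict
pointwise subtractions — mismatched grids are an error, never implicitly
resampled. Band onset uses a threshold criterion (first crossing of 2% of
the maximum, scanning from short wavelength); the onset fraction is a
package parameter with no external reference value. Peaks of congested
sub-320 nm regions are reported from a 3-point local-maximum test and
labelled provisional.

## Potency statistics

Potency is ln(IC50 in nM) throughout; mixed units are refused rather than
guessed (µM data must be converted explicitly). With n = 5 compounds the
report contains Pearson r, Spearman ρ and an exact rank statement
(`monotone_consistent`: descriptor ranks identical or exactly reversed
vs ln IC50 ranks); p-values would be meaningless at this n and are not
computed, and no trend line is fit since no functional form is claimed.
Zero-variance inputs yield explicitly flagged undefined coefficients, not
NaNs. The blue-shift/potency summary evaluates the literal separation
statement: every blue-shifted compound more potent than every red-shifted
one.

## Synthetic data generator

The generator emulates the study's data shapes with exact bookkeeping:

- **Composition:** five compounds (X = H, F, Cl, Br, I), five minima each
  (global minimum + exponential-tail strain energies truncated at
  3 kcal/mol, emulating a few low-lying conformers), a crystal reference at
  0.8–9 kcal/mol, 30 excited states per structure.
- **Geometry:** a hard-coded idealized heavy-atom 4-anilinoquinazoline
  scaffold (two fused aromatic hexagons, N-H anilino bridge, X-phenyl ring,
  two methoxy arms; 1.40 Å bonds). Its only degrees of freedom are the
  anilino-phenyl dihedral and the methoxy torsions, so the crystal pose's
  RMSD ground truth is exactly the applied perturbation. Chemical realism
  is deliberately absent — only the transform bookkeeping must be exact.
- **Spectra:** one principal band near 330 nm with *f* drawn in 0.5–0.7
  plus 29 weak states (180–318 nm, *f* < 0.45), so the *f* ≥ 0.5 rule always
  selects the principal band; spec validation rejects parameterizations
  that could break this invariant.
- **Links:** global-minimum dipoles default to the real series' values and
  map linearly (slope −2.94 per Debye) to a true ln IC50, to which Gaussian
  noise (sd 0.3 ln units, ≈ ±35% in IC50 — a realistic assay spread) is
  added for the *observed* IC50. The two most potent compounds receive blue
  crystal shifts and the rest red, with |Δλmax| drawn from the observed
  1.1–3.3 nm range; the crystal band is displaced by that signed shift plus
  0.5 nm Gaussian jitter (about the wavelength reproducibility one expects
  between nearly-degenerate excited-state solutions). Crystal distortion
  angles (4–42°) increase with potency so the RMSD ordering carries signal.

`recovery_check` re-derives shift signs, strain ordering, population
ranking and crystal RMSD through the public pipeline and names every
mismatch. At the default noise level the Δλ sign is recoverable in ≥95% of
compounds (measured over 200 seeded replicates; the binding constraint is
the 0.5 nm jitter against the ≥1.1 nm minimum shift magnitude).

What passing synthetic recovery shows: the pipeline's bookkeeping —
units, sign conventions, orderings, alignment frames — is internally
consistent end to end, through file round-trips. What it does not show:
that real TD-DFT spectra have a clean single dominant band (they can have
near-degenerate principal transitions that split intensity below the 0.5
threshold), that real crystal distortions are single-torsion, or anything
about the physics linking dipole moments to binding.

## Numerical conventions and degenerate inputs

- Hartree→kcal/mol factor 627.509474, R = 0.0019872041 kcal mol⁻¹ K⁻¹,
  eV·nm product 1239.841984.
- Population normalization holds to 1e−9 for any input; strain of the
  global minimum is pinned to exactly 0.
- λmax ties broken by larger *f*; Spearman ties use midranks.
- Collinear anchor/superposition point sets, empty stick tables, negative
  oscillator strengths, non-positive IC50s or temperatures, duplicate
  conformer labels and double global-minimum tags are all hard validation
  errors naming the offender.
- The pipeline isolates per-compound failures (reported on the result and
  as a nonzero CLI exit) instead of aborting the batch run.

## Problem sizes

The test suite and the acceptance script run the five-compound series with
five conformers + crystal per compound and 30 states per spectrum — the
study's own scale — and 200 generator replicates for the noise Monte
Carlo; the brute-force superposition oracle uses ≤6-atom toys with a 15°
Euler grid plus Nelder-Mead refinement, which locates the global optimum to
well under the 1e−3 Å comparison tolerance.

## Known limitations

- The crystal-pose coordinates of the real series are not redistributable,
  so the published RMSDs (0.135–0.692 Å) serve as context, not as
  regression targets; structural code is validated by oracle equivalence
  and generator ground truth instead.
- No vibronic structure, solvent-shift modelling or emission spectra.
- No free-energy corrections or conformational entropy.
- Alignment assumes identical atom ordering (or an explicit mapping); there
  is no maximum-common-substructure or symmetry-corrected RMSD.
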