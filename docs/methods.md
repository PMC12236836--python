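# Methods

`shellsaxs` predicts small-angle X-ray scattering (SAXS) from explicit
solute+solvent configuration ensembles and decomposes the resulting
contrast into bare-protein and hydration-shell contributions as a function
of temperature.  This note records the models, conventions, numerical
choices, and limitations behind the implementation.

## Scattering model

For each frame *t* of an ensemble, the coherent scattering amplitude over
the atoms selected by the envelope (below) is

    A_t(q) = sum_j f_j(|q|) exp(i q . r_jt),

with Cromer–Mann atomic form factors

    f(q) = sum_{i=1..4} a_i exp(-b_i (q/4pi)^2) + c.

Coefficients are the International Tables four-Gaussian fits as shipped by
gemmi, evaluated here in float64.  The momentum-transfer convention is
q = 4 pi sin(theta)/lambda, so the Gaussian argument is (q/4pi)^2 and
f(0) = Z; this is stated explicitly because a second convention
(s = sin(theta)/lambda) is also common.  Hydrogens scatter with their own
f_H (no united-atom aggregation).  Massless virtual sites of 4-site water
models carry the pseudo-element `DUMMY` with f = 0, and point-scatterer
fixtures carry a flat (q-independent) form factor.  The published
four-Gaussian fits reproduce Z at q = 0 to better than 0.1% for the
organic elements and to ~0.2% for some metals (e.g. Mg); this is a property
of the coefficients, not of the evaluation.

Orientational averaging uses a deterministic Fibonacci-sphere lattice of
unit directions (150 per |q| by default), chosen over random directions for
bit-level reproducibility.  For rigid systems of up to ~8 Å diagonal extent
the 150-direction average agrees with the exact Debye double sum to better
than 1e-3 relative for q ≤ 1 Å⁻¹; the quadrature error grows with q·d, so
wide-angle work on larger systems needs more directions.

## Envelope and buffer subtraction

A fixed spatial envelope — the union of spheres of radius D around the
solute atom positions pooled over all frames — defines which solvent atoms
enter the amplitude sums, identically for the protein system and for a
matched pure-solvent (buffer) box.  D = 12 Å by default so the entire
hydration shell is enclosed; distances are measured from atom centers and
the boundary is closed (distance ≤ D is inside).  Water molecules are
assigned as units by the position of their oxygen so a molecule's electrons
are never split across the boundary.  Envelopes must lie wholly inside the
primary box: coordinates are expected pre-wrapped and no minimum-image
convention is applied anywhere in the analysis.

The buffer-subtracted intensity per direction is

    D(q) = <|A|^2> - |<A>|^2 + |<A> - <B>|^2 - ( <|B|^2> - |<B>|^2 ),

where angle brackets are frame averages and B is the buffer amplitude over
the same envelope.  This is the standard explicit-solvent decomposition:
the variance terms capture solvent fluctuations (and cancel in expectation
between statistically identical sample and buffer solvent), while the
middle term carries the mean solute-plus-shell contrast, giving the forward
limit I(0) = (ΔN_e)².  I(q) is the direction average of D; uncertainties
come from a seeded block bootstrap over frames (20 blocks, 100 replicates
by default).  Two limits are verified by tests: a rigid solute with an
empty buffer reproduces the Debye intensity, and sample ≡ buffer statistics
give I(q) consistent with zero everywhere.

The simulated solvent electron density can be corrected to a target value
(e.g. the experimental 334 e/nm³ at 298.15 K) by uniformly rescaling all
solvent form factors in both sample and buffer by
rho_target / rho_measured, with rho_measured taken from the buffer box.
The alternative correction — adding a Δrho × envelope-transform term to the
buffer amplitude — is not implemented.

## Guinier analysis

ln I(q) = ln I0 − q²Rg²/3 is fitted by weighted least squares (weights
1/σ² on ln I when uncertainties exist) with a self-consistent window:
fit, recompute Rg, truncate to q ≤ qRg_max/Rg, iterate to a fixed point
(a two-window limit cycle, which can occur when a grid point sits exactly
at the bound, is accepted as converged).  The default bound is the
conventional qRg_max = 1.3.  Note that this bound is part of the estimator,
not of the physics: for a homogeneous sphere the ln I curvature inside
qRg = 1.3 biases the fitted Rg by +1.7% (measured on the analytic curve),
which is why the sphere validation fixtures fit with qRg_max = 0.8, where
the truncation bias is below 0.7%.  Non-negative or vanishing low-q slopes
raise a no-Guinier-regime error rather than returning an imaginary Rg.

Experimental-style reduction: repeat curves on a common q grid are averaged
pointwise (σ = standard error over curves), and concentration series are
extrapolated to infinite dilution by a per-q weighted linear regression of
I/c on c, returning the intercept and its standard error.

## Contrast decomposition

With I0 from the Guinier fit, the total contrast ΔN_e = +sqrt(I0)
(positive branch, valid for electron-dense solutes in water; a warning is
raised when the bare-protein contrast is non-positive and the branch
becomes ambiguous) splits additively:

    ΔN_e = ΔN_e_prot + ΔN_e_hs,     ΔN_e_prot = N_e_prot − rho_solv·V_prot.

N_e_prot is the sum of solute form factors at zero angle.  V_prot is the
solvent-excluded volume from a rolling-probe grid construction: voxels
within (r_vdw + probe) of any atom are inflated, then eroded back by the
probe radius via a Euclidean distance transform (defaults: 0.1 Å grid,
1.4 Å probe, Bondi radii).  With probe 0 this reduces to the union of vdW
spheres.  The decomposition depends on the V_prot convention only through a
temperature-independent constant, so shell-water *changes*
ΔN_water(T) = [ΔN_e_hs(T) − ΔN_e_hs(T_ref)]/10 e are convention-free; this
invariance is asserted by test.  The hydration-shell size indicator is
ΔRg = Rg(Guinier) − Rg_prot with Rg_prot the electron-weighted radius of
gyration of the bare solute in vacuo; a contrast-weighted Rg_prot would
differ by a temperature-independent offset under rigid solutes and cancel
in trends.

rho_solv(T) comes either from the measured buffer density or from a bundled
liquid-water table (mass densities, supercooled branch included, converted
at 10 e per 18.015 g/mol; ~333 e/nm³ at 298.15 K with the familiar maximum
near 277 K), linearly interpolated over 243–378 K.

## Synthetic configurations

The generator emulates the *study design* of backbone-restrained
simulations — a rigid solute whose hydration shell alone responds to a
temperature-like control parameter — not liquid water itself.

* **Toy solute**: n atoms quasi-uniform in a ball (default 150 carbons in a
  5 Å ball, ~900 electrons), rigid across frames.
* **Solvent**: rigid 3-site waters (O–H 0.9572 Å, H–O–H 104.52°, optional
  DUMMY 4th site) with centers drawn independently from a piecewise-constant
  density: zero inside the solute vdW region, rho_bulk·(1+ε) within
  `shell_width` (default 3 Å) of the vdW surface, rho_bulk outside
  (default 0.334 e/Å³, i.e. 0.0334 waters/Å³).  Each frame carries a fixed
  water count matched to the integral of that density (estimated by seeded
  Monte Carlo), mirroring canonical-ensemble simulation boxes; sample and
  buffer therefore share identical bulk statistics, and occupancies of
  small sub-regions remain Poisson.  The imposed shell excess is exactly
  N_excess = ε·rho_bulk·V_shell electrons.
* **ε(T)**: linear, zero at the reference temperature (default 300 K),
  slope +0.002 K⁻¹ so shells deplete on heating — the qualitative behaviour
  the pipeline is designed to quantify.
* Everything is bit-reproducible for a fixed seed.

What the generator does *not* contain: water–water correlations (beyond an
optional hard-core O–O exclusion used to exercise the RDF), orientational
structure, force-field energetics, solute flexibility, or periodic-image
effects.  Passing tests therefore validate the contrast bookkeeping,
Guinier extraction, decomposition, and diagnostics — not the realism of any
simulated water model.

Because the generator excludes water oxygens from exactly the vdW union,
parameter-recovery tests decompose with the probe-0 volume, for which the
imposed ε·rho·V_shell is the exact expectation; using the 1.4 Å-probe SES
instead shifts every recovered ΔN_e_hs by the same constant
rho·(V_SES − V_vdW).  Similarly, the toy solute's excluded-solvent term
gives ΔRg a small negative baseline at ε = 0, so shell-induced Rg shifts
are judged relative to that baseline.

## Shell diagnostics

* **3D density maps**: electrons deposited to the nearest voxel, frame
  averaged, divided by voxel volume; difference maps require exactly
  matched grids.  Written as plain-text OpenDX scalar fields readable by
  standard molecular viewers.
* **1D surface-distance profile**: solvent electrons binned by
  d = min_j(|r − r_j| − r_vdw,j) from the solute vdW surface; bin volumes
  are Monte-Carlo estimates of each distance stratum (no closed form exists
  for union-of-spheres offsets).  Bins with zero stratum volume are NaN,
  not zero.
* **Shell-restricted RDF**: g(r) among water oxygens with surface distance
  in [0, x] for x ∈ {3, 5, 7} Å; the ideal-gas normalisation uses pair
  distances of uniform Monte-Carlo points in the *same shell geometry*, not
  the whole box, so g → 1 for uncorrelated solvent regardless of the
  selection shape.
* **Hydrogen bonds**: geometric criterion, donor–acceptor distance ≤ 3.5 Å
  and H–donor–acceptor angle ≤ 30°, the documented defaults of the standard
  trajectory tools; water–water (optionally restricted to within 9 Å of the
  surface) and protein–water selections.
* **Interaction energies**: pairwise protein–water Lennard-Jones
  (Lorentz–Berthelot combination) plus short-range Coulomb
  (k_e = 138.935458 kJ mol⁻¹ nm e⁻²) within a 10 Å cutoff for both terms;
  no mesh or long-range corrections.

## Pipeline and problem sizes

`run_temperature_series` processes each temperature independently with a
seed derived from the run seed (order cannot affect results), producing one
row of (I0, Rg, ΔRg, ΔN_e components, ΔN_water) per temperature plus saved
curves and a resolved config.  The default study sizes — 5 temperatures
over 260–340 K, 100 frames, 30 Å box, 8-point q grid to 0.22 Å⁻¹,
envelope D = 8 Å (sufficient to enclose the 3 Å synthetic shell) — are
chosen so a full series runs in seconds on one CPU while keeping the
shell-contrast signal a few standard errors above the sampling noise; a
production-style configuration (250–375 K in 2.5 K steps, thousands of
frames, D = 12 Å, 101-point q grid to 1 Å⁻¹) is expressible through the
same `RunConfig` fields.

Statistical sanity of the defaults: with 50–100 frames the single-run
standard error of ΔN_e_hs is ~25–35 e (dominated by solvent-number
fluctuations inside the envelope), while the imposed shell signal at
ε = ±0.06 is ~±42 e; averaging over ≥10 seeds separates the ε levels by
several standard errors, which is what the recovery tests assert.

## Known limitations

* Valid at small angles only; no attempt at wide-angle solvent structure
  (q ≳ 2 Å⁻¹) and no hydration-layer or excluded-volume fitting parameters.
* The envelope is center-based union-of-spheres; at very small offsets a
  vdW-surface-based envelope would differ (irrelevant at the ≥8 Å offsets
  used here).
* The density-correction scheme is uniform form-factor rescaling; an
  envelope-transform correction would differ at finite q.
* No periodic-image handling: inputs must be pre-wrapped with the envelope
  inside the box (validated on construction).
* The positive-sqrt branch of I0 fails for solutes less electron-dense than
  the displaced solvent (it warns); temperature series of such systems
  would need the sign resolved externally.
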