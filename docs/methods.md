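# Methods

Units are fixed package-wide: energies in kcal/mol, lengths in nm, times
in ps (residence and decay times reported in ns), mass densities in
g/cm³, diffusion coefficients in 10⁻⁹ m²/s.  Coordinate files (XYZ, PDB,
LAMMPS dump) are read and written in ångströms and converted at I/O.

## Wall potential and combining rules

The wall form is E(z) = ε[(2/15)(σ/z)⁹ − (σ/z)³], the algebra used by
common MD engines for flat 9-3 walls.  Its derived constants follow from
that specific form: zero crossing at (2/15)^(1/6) σ ≈ 0.715 σ, minimum at
(2/5)^(1/6) σ with depth ≈ 1.054 ε.  The 12-6/9-3 cross-interaction σ
rule averages contact distances with the atom's σ rescaled to the 9-3
crossing position, 0.715 σ_iw = (0.715 σ_ii + σ_ww)/2, so that σ_ww
stays directly comparable to an atomic 12-6 σ; for an ideally flat
single-element surface the pipeline then maps the material back to
(approximately) the σ of its constituent atoms.  ε combines by the
geometric mean; probes with ε = 0 (water hydrogens) carry no dispersion
interaction and are rejected.

## Parameterization pipeline

* **z origin.** Probe heights are measured from the plane through the
  centers of the outermost atom layer (`surface_z`).  The true height
  origin of a corrugated surface is not observable; any constant offset
  in this convention is absorbed into the fitted σ_iw, which is why σ_iw
  is reported per surface rather than reused across conventions.
* **Lattice sums.** The probe–slab energy is an open lateral sum:
  periodic images are added in square shells until a full shell changes
  no grid energy by more than `image_tol` (default 1e-4 kcal/mol).  This
  differs deliberately from a fixed pair cutoff; the tolerance, not a
  radius, is the contract.  When a builder records the primitive lateral
  cell, the slab is folded onto it (exact duplicate removal) before
  summing.
* **Scan grid.** Default z range 0.1–1.5 nm in 0.01 nm steps; 36 sites
  as a uniform 6×6 grid over one periodic cell, entered at bin centers.
  Reported per-probe values are site means with standard errors
  s/√n (sample standard deviation, n = 36).
* **9-3 fit window.** From the repulsive shoulder (first z where the
  energy drops below +|well depth|) to where |E| < 1e-4 kcal/mol or the
  scan end, uniform weights.  Initial guesses: ε from the well depth, σ
  from the zero crossing divided by 0.715.  The window choice moves the
  fitted parameters by a few percent because the 9-3 form cannot
  represent a discrete lattice exactly; the residual norm is recorded
  per fit.
* **Combining-rule regression.** Ordinary least squares with the single
  wall parameter as unknown (closed-form solutions); a `weighted` switch
  uses 1/SE² weights instead.

### Reference surfaces

Graphite is built as the AB-stacked crystal (a = 0.2461 nm, interlayer
0.3354 nm), top basal plane at z = 0.  Heptane and tridecane are
pseudo-crystalline slabs of all-trans chains lying parallel to the
surface (C–C 0.1526 nm, C–C–C 112°, C–H 0.109 nm, 0.4 nm end-to-end
gap), packed on a square (y, z) grid whose spacing is solved so the mass
density equals the experimental liquid density at 298 K (0.6795 and
0.7564 g/cm³; configuration inputs, not constants of the code).  The
exact chain packing is a free modelling choice validated only through
the parameterization results.  Slab-atom and probe LJ parameters are
standard published GAFF values plus the SPC/E water oxygen
(`wallmapper.data`).

With these inputs the full pipeline gives σ_ww ≈ 0.32 nm and
ε_ww ≈ 18 kcal/mol for graphite (the carbon σ is 0.34 nm), and
ε_ww(heptane) < ε_ww(tridecane) < ε_ww(graphite) with alkane σ_ww below
every constituent-atom σ — the corrugated chain surfaces present a
closer effective contact than their atoms' own σ.

## Screening model

ρ_int = a − (a − ρ_vac) exp(−c ε_ww σ_ww): bounded in [ρ_vac, a),
monotone in ε_ww, with ρ_vac always a free fitted parameter (a film in
contact with vacuum has no wall zero-crossing from which to measure a
comparable interfacial zone, so the limit is fitted, not imposed).  The
exponent couples ε_ww and σ_ww as a product; one joint (a, ρ_vac, c)
triple is fitted across all σ values by default, matching the single
canonical triple, and per-σ fits can be obtained by filtering the input
grid.  The canonical parameters shipped in `CANONICAL_MODEL` are
a = 0.63 g/cm³, ρ_vac = 0.08 g/cm³ and c = 1.1 mol kcal⁻¹ nm⁻¹
(equivalently 0.11 per kcal/mol per ångström — note the unit: quoting c
per nm makes its numeric value ten times the per-Å figure).  The fit
uses `scipy.optimize.curve_fit` with data-driven initial guesses
(a above the grid maximum, ρ_vac below the minimum, c from the mean of
1/(εσ)); a design with a single distinct ε value is rejected as
degenerate.

## Trajectory analysis

* Interfacial zone: 1 nm from the wall zero crossing 0.715 σ_ww, so
  walls of different σ are compared with equal exclusion zones.
* Density profiles: default bin width 0.02 nm; conservation (sum of
  bins × bin volume = mean total mass) is exact by construction.
  Zone averages weight partial bins by overlap.
* Layers: first layer from the zone start to the density minimum
  between the first two solute peaks (`scipy.signal.find_peaks`); the
  second layer is the adjacent equal-width window.  Fewer than two
  peaks is an error so callers can fall back to fixed widths
  deliberately rather than silently.
* Bulk boundary: centered moving average (default 5 bins), numerical
  derivative, boundary at the first z where |dρ/dz| stays below the
  tolerance for a full smoothing window.  On profiles with residual
  oscillations the detector triggers at the first node whose flat
  stretch spans the window — the window length is therefore the
  resolution limit of the method.
* Reference site for layer membership: the bond midpoint for molecules
  with a bond vector, else the particle itself.  Residency is strict
  continuous occupancy (no excursion tolerance); an origin–lag pair
  contributes only if the molecule stays inside for the whole interval.
* MSD: multi-time-origin over x, y only, FFT-based per residency run,
  laterally unwrapped (z is never wrapped; the normal direction is not
  periodic).  D = slope/(2n), n = 2, fitted by default over lags in
  10–30% of the maximum lag; a curvature flag marks windows whose two
  halves disagree in slope by >25% (ballistic or saturating regimes).
* Residence times: a visit of k consecutive frames counts k·Δt, so
  total visit time equals total occupancy exactly.  Visits touching
  either trajectory end are censored: histogrammed but excluded from
  means by default.
* Bond ACF: multi-origin average of the unit bond-vector dot product;
  decay time at the first 1/e crossing, linearly interpolated between
  bracketing lags; reported as `None` when not reached.
* Film-size extrapolation: OLS of ρ_int against 1/L; the intercept is
  the infinite-thickness estimate and with a negative slope necessarily
  exceeds every finite-film value.

## Synthetic film generator

The generator emulates a solution film against a flat wall: labeled
non-interacting particles and rigid two-site dumbbells under overdamped
Euler–Maruyama dynamics, force from the 9-3 field (built from the wall
parameters and a solute LJ type via the package combining rules) acting
on z only, lateral periodic wrapping, reflective film top standing in
for the liquid–vacuum surface, and a reflective numerical floor at
0.3 σ where the repulsion exceeds any relevant energy.  Orientations
diffuse on the sphere (tangential Gaussian steps, renormalized).
Defaults mirror the film geometry the screening grid refers to:
3.45 × 3.45 nm² cross-section, 3.1 nm thickness, 298 K, tridecane wall,
glycine-like solute (ε 0.11 kcal/mol, σ 0.30 nm, mass 75.07 amu),
D_trans 0.5 × 10⁻⁹ m²/s and D_rot 2 ns⁻¹ (the order of measured bulk
glycine mobilities).  Initial positions are drawn from the exact
equilibrium distribution, so trajectories are stationary from frame 0;
a fixed seed gives bitwise-identical output.

Ground truth: the equilibrium z-density ∝ exp(−U(z)/kT) in closed form,
the planted diffusivities, and the bond-ACF 1/e time 1/(2 D_rot).
What the generator deliberately omits: solute–solute and solute–solvent
interactions (no layering peaks, no concentration-dependent slowdown,
no clustering), inertia, and capillary fluctuations of the free
surface.  Passing analyzer tests therefore demonstrates estimator
correctness on known ground truth, not fidelity of any particular force
field; conversely the analyzers make no assumption the generator is
needed to satisfy beyond positions/orientations on a uniform time grid.

A first-order Euler–Maruyama scheme slightly distorts the stationary
density where the force varies strongly over one step; equilibrium
checks therefore use the exact sampler (`sample_boltzmann`), and the
dynamical integrator refuses dt when the rms step exceeds a quarter of
the wall zero crossing.

## Problem sizes in the test suite

Acceptance-grade checks are sized to run on one CPU in a few minutes:
the graphite pipeline uses the full 6×6 grid with all seven probes; the
three-material ordering check uses a four-probe subset on a 3×3 grid
(which still resolves the alkane chain corrugation); the continuum
half-space oracle uses a 0.03 nm simple-cubic lattice, 0.9 nm laterally
and 2 nm deep, with the image sum converged to 0.02 kcal/mol (≈4×10⁻⁵
of the well depth); analyzer oracles use 10⁶ equilibrium samples and
10³–10⁴-step Brownian runs with fixed seeds.

## Known limitations

* The 9-3 form cannot represent a discrete lattice exactly; fitted
  (ε_iw, σ_iw) depend at the few-percent level on the fit window and on
  the z-origin convention.  Between the wall's zero crossing and its
  minimum a lattice deviates from the smeared continuum by up to ~6% of
  the well depth at 0.03 nm spacing (a boundary term that vanishes with
  the spacing).
* Electrostatic wall terms are out of scope; the mapping covers
  dispersion-dominated surfaces.
* The screening model's canonical parameters apply to one film
  thickness and concentration; thicker films need the bulk-boundary
  detector and the 1/L extrapolation instead of the fixed 1-nm zone.
* The alkane slab builder produces one idealized packing; real liquid
  surfaces are rougher, which lowers the effective σ_ww further.
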