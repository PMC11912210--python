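# Methods

## Scope and model

`ramaibi` parametrizes the backbone dihedral potential of an amino-acid
residue against a target Ramachandran distribution and scores candidate
distributions against spectroscopic observables.  The potential is the
separable Amber proper-dihedral form

    V(phi, psi) = sum_{n=1..N} k_n [1 + cos(n*phi - gamma_n)]
                + sum_{m=1..M} k_m [1 + cos(m*psi - gamma_m)] + c,

with N = M = 5 terms by default, coefficients in kJ/mol and per-term
phases in degrees.  Phases restricted to {0, 180} give pure cosine
series, which are even in each angle and therefore can only represent
distributions symmetric under phi -> -phi and psi -> -psi separately
(appropriate for an achiral glycine residue).  Chiral residues require
the sine components; these are admitted through free per-term phases.
The additive constant `c` is fitted and stored but never exported — it
is physically irrelevant, and the Boltzmann map is gauge-invariant
under it.

Because `k cos(n t - g) = a cos(n t) + b sin(n t)` with
`a = k cos g, b = k sin g`, the free-phase fitting problem is an
ordinary linear least-squares problem in `(a, b)` per term.  We solve
it exactly with `numpy.linalg.lstsq` (numerically equivalent to the
normal equations) and convert back to amplitude/phase form with
`k = hypot(a, b) >= 0`, `gamma = atan2(b, a)`.  The `(a, b)`
representation is also the canonical one for comparing potentials,
since `(k, gamma)` and `(-k, gamma + 180)` describe the same function.
Potentials are likewise added term-by-term in `(a, b)` space during the
update step, with the additive constant corrected so that the total
energy function (not just its periodic part) is the exact sum.

## Grids and distributions

Angles live on the (phi, psi) torus in degrees.  The working grid uses
square bins of width 2 degrees by default, bin centers at -179, -177,
..., 179 on each axis (180 x 180 = 32400 bins).  A sample at angle `a`
belongs to the bin whose center `c` satisfies `c - 1 <= a < c + 1`;
+180 wraps onto the -180 side, so every angle lands in exactly one bin.
Distributions are validated (non-negative, total mass 1 within 1e-9)
but never silently renormalized, which keeps file round trips
bit-faithful.

The Hellinger distance is computed in the numerically stable form
`H = sqrt(0.5 * sum (sqrt(p) - sqrt(q))^2)`, mathematically identical
to `sqrt(1 - BC)` with the Bhattacharyya coefficient BC, but exactly
zero for identical inputs and insensitive to the ~1e-9 slack in the
normalization.  Similarity classes follow the standard criteria:
H <= 0.1 very similar, 0.1 < H <= 0.25 moderately similar,
0.25 < H <= 0.4 moderately dissimilar, H > 0.4 very dissimilar.

### Mesostates

Seven rectangular regions (pPII, antiparallel beta, transitional beta,
right-handed helix, two beta-turn windows, asx) are built in with
strict-inequality membership tested at bin centers.  Populations are
region probability masses; region free energies are population-weighted
means of `-kB T ln(p / p_ref)` with `p_ref = 1/n_bins`, empty bins
contributing zero, so an unoccupied region reports zero free energy
rather than a divergent one.  Note that the printed helix region
(psi < -14) and the type I/II' beta_{i+2} turn window (psi > -20)
overlap on a 6-degree psi strip; mass there is counted in both regions,
while `other_fraction` is always measured against the union.  The
populations-plus-other sum equals one exactly only for ensembles with
no mass in that strip.

## Gaussian superposition model

A residue ensemble is a weighted sum of axis-aligned two-dimensional
Gaussians, one per mesostate, with weights equal to mesostate mole
fractions and per-axis half-widths interpreted as standard deviations.
Densities are wrapped onto the torus by summing images shifted by
+/-360 degrees per axis (nine images); for sigma <= 60 degrees the
truncation error is below 1e-12 of the peak.  No within-component
phi-psi correlation term is used: only per-axis widths are specified.
The sampler draws a component per weight and a wrapped normal deviate
per axis, deterministically given a seed.  Fitting model parameters to
experimental data is out of scope; models are inputs.

## Observables

**J-couplings.**  `J(theta) = A cos^2(theta + theta0) + B cos(theta +
theta0) + C` with per-coupling constants supplied as data.  The shipped
table uses the self-consistent Hu–Bax parameters for the five
phi-dependent 3J couplings and the Wirmer–Schwalbe psi-dependent
relation for 1J(N,CA); the file is editable and the parameter
uncertainties in it are plausible defaults, not asserted values.
Ensemble averages are midpoint sums over bin centers; because the
integrands are smooth and periodic, the 2-degree midpoint rule is
accurate to well below 1e-4 Hz (verified against 0.25-degree
quadrature).

**Uncertainties.**  The per-coupling uncertainty combines the Karplus
parameter errors and the experimental error pointwise in quadrature,
`s(theta) = sqrt((s_A cos^2)^2 + (s_B cos)^2 + s_C^2 + s_J^2)`, then
ensemble-averages; this is the standard propagation for independent
parameter errors and is isolated in one function so an alternative
combination rule can be swapped in.  It guarantees `s_i >= s_J`.  For
couplings without published parameter uncertainties (1J(N,CA)) the
experimental `s_J` is used alone.

**Reduced chi-squared.**  `chi2 = (1/N) sum ((J_calc - J_exp)/s_i)^2`,
reported for all couplings and for the phi-dependent subset.  The
1/N (not 1/(N-1)) normalization is used throughout.

**VCD amide I'.**  A degenerate two-oscillator exciton model: per
conformer the inter-dipole angle is `delta = phi + psi` (configurable),
the coupling splits the band by `+/- V = J0 cos(delta)` and the two
exciton modes carry rotational strengths `-/+ (R0/2) sin(delta)` — a
conservative couplet whose strengths sum to zero exactly.  Profiles are
population averages convolved with a peak-normalized Gaussian (default)
or Lorentzian line.  The orientation rule is odd under conformer
inversion, so an inversion-symmetric (achiral, glycine-like) ensemble
is exactly silent — the built-in consistency check for the model.  All
constants (intrinsic wavenumber 1658 cm^-1, coupling scale 5 cm^-1,
half-width 12 cm^-1, strength scale) are configuration; the defaults
are a generic stand-in for published coupled-oscillator
parametrizations, adequate for couplet-shape scoring but not for
absolute intensities.

## Iterative Boltzmann inversion

Each iteration samples the current potential, forms the
potential-of-mean-force difference `dV = kB T ln(P_sampled/P_target)`
on bins where both probabilities exceed a floor, fits the separable
Fourier form to `dV` by unweighted least squares over the unmasked
bins, and updates `k <- k + lambda dk` (damping lambda = 1 by default).
Positive `dV` marks over-populated bins, so adding it suppresses them.
Convergence is declared at Hellinger(P_sampled, P_target) <= 0.01 by
default; non-convergence returns the best state flagged, never raises.
Temperature defaults to 300 K with kB = 0.0083144621 kJ/(mol K);
angles are degrees externally and radians internally.

With the exact sampler (the closed-form Boltzmann distribution — exact
because the modeled system is a single (phi, psi) pair) and an in-span
target, the first undamped step is already the solution: `dV` from the
flat start equals `-kB T ln P_target` up to a constant, and the fit is
linear.  This is the fixed-point structure the loop is built around,
and the package's headline test: random in-span 5-term potentials with
|k| <= 3 kJ/mol are recovered to ~1e-15 kJ/mol in one iteration.

**Probability floor.**  The default floor is 1e-8, masking (not
clamping) bins before the logarithm so the fit is not biased toward an
arbitrary floor value.  For histogram samplers the floor should be set
to the sampling resolution (1/n_samples): with a lower floor,
target-tail bins that catch a single stray sample contribute
`+kB T ln(~100)` outliers that visibly destabilize the unweighted fit.

**Metropolis surrogate.**  For realistic-noise testing a Metropolis
random walk on the torus is provided: 100 independent walkers advanced
in parallel, uniform proposals of +/-25 degrees per angle, acceptance
min(1, exp(-dV/kBT)), the first 100 sweeps per walker discarded as
burn-in, visited states histogrammed.  It is deterministic given its
seed and raises if 10^4 consecutive proposals are rejected.

**Variance-matched binning.**  A histogram of 10^6 correlated samples
on the 32400-bin grid has ~30 counts per bin; its Hellinger distance to
the true distribution is then dominated by multinomial noise (~0.04 for
iid draws, worse with chain autocorrelation) regardless of how well the
potential fits.  Stochastic-sampler demonstrations therefore use a
5-degree working grid (5184 bins, >= ~100 expected counts per occupied
bin), on which the inversion of the alanine-like fixture converges in
one iteration to H ~ 0.03.  The inversion machinery itself is
grid-agnostic; the 2-degree grid remains the default for exact-sampler
and scoring work.

## Synthetic fixtures

`glycine_like` places components in mirror pairs at +/-(center) with
equal weights, making the density exactly inversion-symmetric — the
achiral reference for the VCD silence check.  `alanine_like` is chiral
and pPII-dominated: three extended-region basins (pPII 0.62 at
(-70, 140), transitional beta 0.18 at (-110, 140), antiparallel beta
0.20 at (-155, 140)) sharing one broad psi profile (sigma 22 degrees).
The shared psi profile keeps the ensemble essentially a product
distribution and hence inside the reach of a separable dihedral
potential — the regime in which the alanine-like reparametrization
converges in a single inversion step; minor helical/turn populations
are deliberately omitted, since even a few percent of helical weight
introduces phi-psi coupling that no separable potential can represent
(best attainable Hellinger ~0.15-0.35).  The parameter values are
illustrative, not fits to any experimental data set.

Synthetic experiments forward-model J-couplings and a VCD profile from
a known ensemble and add Gaussian noise.  By default the noise standard
deviation per coupling equals the full propagated uncertainty s_i
("noise-matched"), so scoring the generating model against its own
experiment is chi-squared-calibrated: the mean reduced chi2 over many
realizations is 1 by construction.  Drawing with the experimental s_J
only, or no noise, is available.  What the fixtures do not emulate:
multi-residue context and neighbor effects, within-component phi-psi
correlation, solvent or force-field specifics, and real experimental
baselines — passing tests demonstrate the correctness of the inversion
and scoring machinery, not agreement with any laboratory data.

## Problem sizes and determinism

Default test and acceptance sizes: 32400-bin grids for exact-sampler
and observable work; 20 random potentials for the recovery check; 10^6
Metropolis steps per iteration and a 5-degree grid for the stochastic
inversion; 200 noise realizations for the chi-squared calibration; 100
random triples for the metric axioms.  Every stochastic component takes
an explicit seed (NumPy `default_rng`), and all reported quantities are
recomputed at run time by `scripts/acceptance.py`.

## Known limitations

- Separable potentials cannot represent phi-psi-correlated targets;
  the loop then converges to the best separable approximation and
  reports non-convergence (by design).  CMAP-style correlation terms
  are out of scope.
- Prime-angle potentials V(phi', psi') are not fitted; the exporter can
  emit explicit zeros only.
- The VCD model is a two-oscillator approximation with configurable
  constants; it is not a parametrized reproduction of any published
  exciton Hamiltonian.
- Mesostate free energies depend on the uniform-reference convention
  described above and are not comparable across grids of different
  bin width.
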