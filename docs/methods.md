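# Methods

## The assembly model

`ringpool` models the self-association of a ring-forming single-strand-
annealing protein (human RAD52 and its C-terminally truncated construct)
as **isodesmic growth with preferential cyclization**.

Open chains grow noncooperatively: every monomer-addition step shares a
single dissociation constant `Kd`, so with free-monomer concentration
`c1` and `x = c1/Kd` the open n-mer species concentration follows the
geometric chain law

    c_open(n) = Kd * x^n .

An open n-mer can close into a ring by forming one extra bond without
adding a subunit.  Because the growing polymer is semiflexible with a
preferred curvature, closure is easiest at an optimal protomer number
`n_opt`; deviations cost Hookean bending energy.  The closure
equilibrium constant is

    Kc(n) = Kc0 * exp(-E_b(n)),   E_b(n) = ((n - n_opt)/sigma_ring)^2 / 2 ,

with `E_b` in units of kB*T and `sigma_ring` the SD of the ring protomer
number (`sigma_ring^-2` is proportional to the bending stiffness).
Closed-ring species concentrations are `c_ring(n) = Kc(n) * c_open(n)`.
The free energy gain of closure at the optimum is `ln(Kc0)` kB*T;
temperature never enters numerically because all energies are expressed
in kB*T.

Given a total protomer concentration `c_total` the free monomer is found
by inverting the mass balance

    c_total = sum_n n * c_open(n) * (1 + Kc(n)*[n >= n_ring_min]) ,

which is strictly increasing in `c1`, so a bracketing root finder
(`brentq`, relative tolerance at machine precision) is guaranteed to
converge; solved distributions conserve protomer mass to better than
1e-9 relative.

Defaults `n_max = 25` and `n_ring_min = 3`: the Gaussian in `Kc(n)`
makes rings far from `n_opt ~ 10.8` negligible (a trimer ring carries
~49 kB*T of strain), and truncation at 25 leaves less than 1e-12 of the
mass unaccounted at the fitted parameters.  Pool definitions follow the
experimental analysis: the "short" (dilute) pool sums open species of
sizes 1-4, the ring pool sums closed rings of sizes 8-12.  Both are
configurable.  The reported ring pool counts closed rings only; at
`Kc0 ~ 1.9e6` open chains of ring sizes are a ~1e-6 correction and are
tracked separately in the distribution object.

Multi-ring clusters (species at 2x and 3x the ring mass seen in mass
histograms) are outside the thermodynamic model; the deconvolution
labels them and the count conversion excludes them.

### Critical concentration

Above a threshold the model behaves like a condensation transition: the
ring pool grows almost linearly with total concentration while the
dilute pool stays nearly constant (the "reservoir").  Two descriptions
of the threshold are implemented:

* **Empirical line** (`EmpiricalRingModel`): weighted least squares of
  `c_ring = (c_protomer - c_crit)/n_avg`; the slope gives the average
  protomers per ring, the x-intercept the critical concentration, with
  delta-method standard errors (statsmodels WLS underneath).  Above the
  threshold the short-pool plateau should approximately equal `c_crit`.
* **Maximum curvature** (`critical_concentration`): the model ring pool
  is evaluated on a log-spaced grid (default 0.1-50 nM, 400 points) and
  the total concentration maximizing the central-difference second
  derivative is returned.  The location is stable to grid refinement
  within 10%; the default grid resolves it to ~2% near 2 nM.

### Global fit

`RingAssemblyModel` fits (`Kd`, `Kc0`, `n_opt`, `sigma_ring`) to a tidy
titration table of per-size species concentrations at several total
concentrations.  Open and closed species of the same size are summed in
the prediction because they are indistinguishable by mass.  Choices:

* residuals weighted by `1/sqrt(max(count, 1))` — the Poisson-motivated
  scheme when concentrations derive from event counts;
* `Kd` and `Kc0` are fitted in log10 space with bounds
  (0.1-1000 nM, 1-1e12, n_opt 5-20, sigma 0.1-5); bound-hitting
  parameters are flagged in the results;
* 10 seeded multistarts (Gaussian jitter of the start in packed
  coordinates) guard against local minima; the start itself is always
  one of the candidates, so the optimum can never be worse than it;
* uncertainties by nonparametric bootstrap over replicate readings
  (default 200 resamples, seeded, warm-started at the point estimate).

## Histogram deconvolution

A mass-photometry reading is a list of single-particle masses.  The
per-oligomer abundances are obtained by fitting a sum of Gaussians to
the 4 kDa-binned histogram, under the instrument constraints:

* component centers start at integer multiples of the monomer mass and
  may move at most 0.45 monomer masses, so peak identity cannot swap;
* component SDs are bounded above by the calibration line
  `sd(m) = sd_slope*m + sd_intercept` evaluated at the fitted center
  (enforced by corrective refits when a center drifts); narrower peaks
  are allowed — a well-defined oligomer can undercut the calibration
  standards — but wider ones are not;
* residuals are Pearson-weighted (`1/sqrt(max(count,1))`) so the
  Poisson bin noise is homoscedastic;
* bins are modeled by the exact Gaussian mass within each bin (CDF
  differences), not a midpoint density.

Components are added by stepwise forward selection: each new component
starts at the monomer multiple with the largest positive residual mass
(matching pursuit, warm-started from the previous fit) and is kept only
if it improves the Akaike information criterion.  For these
variance-weighted fits the AIC is the deviance form `chi^2 + 2p` with
the small-sample (AICc) correction using the number of populated bins;
this keeps near-degenerate neighbor components of a single broad peak
out of the model, which the unweighted `N ln(RSS/N)` form does not.
Ties within 1e-9 resolve to fewer components.  After selection, peaks
below 2% of the fitted area are removed and fractions renormalized.
Peaks beyond `n_max` monomer multiples are labeled clusters and excluded
from downstream tables.

Counts become species concentrations assuming equal per-particle
landing probability: `c_i = f_i * S` with the scale `S` fixed by
protomer mass balance against the nominal total concentration.  No
mass-dependent landing correction is applied (none is established for
the instrument class); if landing rates do depend on mass, recovered
abundances are biased accordingly.

## Synthetic data

The generator reproduces the acquisition statistics of the study
conditions, and these defaults are fixed: titration at 10, 25, 50, 100
and 200 nM, four replicate 60-s readings per concentration, 2000 events
drawn per reading, monomer mass 48.4 kDa (full-length; the truncated
construct is 25.3 kDa), detection floor 40 kDa, upper limit 5 MDa, and
the fitted parameters (Kd = 14 nM, Kc0 = 1.9e6, n_opt = 10.8,
sigma_ring = 0.79) as ground truth.  Events are independent draws:
species are sampled in proportion to their particle concentrations, the
ideal mass is `n * monomer_mass`, and Gaussian noise with
SD = `sd_slope*m + sd_intercept` (defaults 0.05 and 5 kDa, i.e. 10 kDa
at 100 kDa — a typical single-particle interferometric calibration) is
added.  Sub-floor events are discarded and *not* replaced, mimicking
real count loss; discards are recorded in the metadata.  An optional
contaminant fraction places events at 2x and 3x the optimal ring mass
to exercise cluster handling (default 0).

What the generator does **not** emulate: surface crowding or depletion
during a reading, mass-dependent landing probabilities, day-to-day
calibration drift, non-Gaussian contrast noise, DNA-bound mass shifts,
and >1.5 MDa aggregates.  Passing recovery tests therefore demonstrate
correctness of the estimation chain under the stated noise model, not
robustness to instrument systematics absent from it.

Binding curves are Hill isotherms `theta = c^H/(K^H + c^H)` with
additive Gaussian noise clipped to [0, 1]; annealing time courses are
single exponentials `A*(1 - exp(-k t))`.  Both are seeded and
reproducible.

## Kinetics calculators

* `HillBindingModel`: weighted nonlinear least squares of the Hill
  equation (per-point SEs as sigma, matching error-bar-weighted fitting
  of gel data); flat curves are rejected as non-identifiable.
* `AnnealingKineticsModel`: single exponential with free amplitude;
  rates are reported in min^-1 and s^-1, and an enhancement factor is
  computed against a protein-free hybridization control when given.
  Input normalization (band intensities to controls) is assumed done.
* `off_rate(kd, k_on)` = `Kd*k_on` with explicit concentration units;
  the default `k_on = 1e8 /M/s` is the diffusion-limited order of
  magnitude and always overridable.
* `scaled_kd(kd, delta_n, f=0.34)`: each additional bound protomer
  multiplies the DNA dissociation constant by `f`; 0.34 is a
  cross-protein estimate from the Red-beta homologue and is exposed as
  a parameter, never hard-coded into reports.
* `ring_closure_energy(kc0)` = `ln(Kc0)` in kB*T.

## Problem sizes and determinism

The test suite and the acceptance script run the full study-scale
pipeline (5 concentrations x 4 replicates x 2000 events, ~40k events)
once per seed; one end-to-end run takes tens of seconds on a single
core.  Property tests use smaller event counts where the property does
not require scale.  All randomness flows through
`numpy.random.default_rng` seeded from user-supplied integers; repeated
runs with the same seed are byte-identical, including CLI outputs
(reports embed the tool version, a config hash and the seed).

## Known limitations

* The ring-size composition recovered from deconvolved histograms is
  blurred by peak overlap in the ring region (adjacent ring sizes are
  separated by one monomer mass but have SDs of ~25-30 kDa), so
  `n_opt` and especially `sigma_ring` are recovered with upward bias on
  synthetic data; `Kd` — anchored by the well-resolved short-oligomer
  region — is recovered within ~10%.
* Species present below the 2% area rule in a reading (for example
  single ring sizes near 10 nM total) drop out of that reading's
  titration rows; the global fit simply has no observation there.
* The fold-excess of the dilute pool over the ring pool at low
  concentration is extremely sensitive to the parameters (it varies
  ~2.5x across the quoted 1-sigma parameter ranges), so downstream
  users should propagate parameter uncertainty before interpreting it.
* The model contains no DNA-bound species, no kinetics of assembly and
  no multi-ring cluster thermodynamics, by design.
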