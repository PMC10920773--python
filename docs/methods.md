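# Methods

## Model

The community model couples four populations in a well-mixed near-surface
water parcel: susceptible *Prochlorococcus* (S), virally infected cells
(I), free T4/T7-like cyanophage (V) and heterotrophic nanoflagellate
grazers (G), all in number per litre, time in days with t = 0 anchored at
06:00 local (noon at t mod 1 = 0.25, midnight at 0.75).

Division is light-driven and sinusoidal, `mu(t) = mu_ave (1 + delta_mu
sin(2 pi (t + delta_t)))`, so `delta_mu ∈ [0, 1]` guarantees a nonnegative
rate and the daily mean is exactly `mu_ave`. Infection transfers cells
from S to I at rate `phi·S·V`; lysis releases `beta` virions per cell at
rate `eta·I` (mean latent period `1/eta`); grazing `psi·(S+I)·G` is
indiscriminate between infected and healthy cells. Each population carries
a quadratic self-limitation (`m_P`, `m_V`, `m_G`) standing in for
unresolved density-dependent processes; these closures avoid structurally
favouring either predator. Grazer growth converts consumed cells with an
effective gross growth efficiency `e_eff` — the product of GGE and the
prey:grazer nitrogen-quota ratio, which only ever enters the dynamics as
one number and is therefore one parameter — plus a generalist term
`gamma·G` for growth on other prey. `gamma ∈ {0, 0.01, 0.05, 0.1, 0.2,
0.5}`/day spans the specialist–generalist gradient; it is fixed per model
variant, not inferred.

The diel-adsorption variant multiplies `phi` by a mean-preserving step
function: 0.5 from midnight to noon, 1.5 from noon to midnight, switch
instants belonging to the interval they begin. Both the infection flux and
the adsorption sink on V use the same time-dependent rate — they are one
physical process. (Whether the sink should also vary is not observable;
keeping a single process is the parsimonious reading, and the multiplier
is configurable.)

## Numerics

Two integration paths. The user-facing default is scipy's adaptive
Runge–Kutta (`solve_ivp`, rtol 1e-8, atol 1e-2 cells/L), integrating
piecewise between the quarter-day forcing switches so the step controller
never crosses a discontinuity. The inference and sweep engine is a
numba-jitted classical RK4 with fixed steps aligned to the quarter-day
grid (240/day default; 96/day in likelihoods, where the hourly observation
grid sets the resolution). At these scales the dynamics are smooth and
non-stiff; the fixed-step solution agrees with a tight-tolerance adaptive
run to ~1e-10 relative error (tested), and one 12-day evaluation costs
under a millisecond, which is what makes desk-scale MCMC possible.

Integrator undershoot more negative than the absolute tolerance raises an
error rather than being clipped; smaller undershoot is set to zero.
Abundances above 1e15 /L abort with a diagnostic (runaway sweep points).
Extinction is declared when total *Prochlorococcus* drops strictly below 1
cell/L, and is reported, not raised, in burn-in runs and sweeps.
Stationarity after burn-in (default 1000 days, two extra days simulated)
means the state one day apart differs by < 1e-3 relative, everywhere on
the comparison day — the attractor is a diel cycle, not a fixed point.

## Default parameters and the synthetic generator

The shipped defaults (`DEFAULT_TRUE_PARAMS`) are implementer-chosen to
reproduce the qualitative field regime of the system the model was built
for: total cells ~1e8 /L with a night-time peak and a few-percent diel
range, ~1.5% infected cells, ~1e9 virions/L, ~1e6 grazers/L, grazing
taking ~89% of cell losses against ~6% lysis and ~5% other, grazer
residence ~17 days, virion residence ~2 days. They are a coexistence
point, not fitted values.

The generator emulates the observation structure of a 12-day cruise:
hourly (configurable down to 3-minute) cell counts, 4-hourly bottle
signals, a per-signal linear trend centred mid-cruise (default slopes
−1.5e6 cells/L/day, +2e7 virions/L/day, +1.5e4 grazers/L/day, +0.02
percentage points/day), and observation noise — multiplicative lognormal
on abundances (sigma 0.10–0.15 by default, 0.02–0.03 in the low-noise
preset used for recovery experiments), additive Gaussian truncated to
[0, 100] on the infected percentage (0.5 pp default, 0.1 pp low-noise).
What it does *not* emulate: instrument-level artifacts (cytometer gating,
assay error structure), gaps and outliers, autocorrelated noise, or any
process the model itself lacks (size structure, nutrient limitation,
mixotrophy). Passing recovery tests therefore demonstrates that the
inference machinery is calibrated against the model's own data-generating
process — not that the model is a complete description of field data.

## Detrending and the likelihood

Models are fitted against detrended data: a linear (configurable:
constant, quadratic, lowess) trend is fitted per signal by least squares
and its *anomaly* — the fitted trend minus its window mean — is subtracted
from the data; the model series gets the identical treatment with its own
fitted trend. Removing the anomaly rather than the full fitted line is
deliberate: subtracting each side's intercept too would cancel all
absolute-magnitude information and leave every population scale
unidentified, whereas the fits are meant to reproduce the magnitudes of
the series as well as their diel variation. (The standalone
`observations.detrend` helper subtracts the full fitted trend, with
`retrend` as its exact inverse for visualisation; the anomaly convention
lives in the likelihood.)

Residuals enter independent Gaussians with per-signal noise scales that
are, by default, inferred alongside the parameters under half-normal
hyperpriors scaled to the detrended data's spread; fixed scales and
analytic (Jeffreys) marginalisation are alternatives. Initial conditions
at t = 0 are four additional inferred quantities with priors centred on
the first observations (log-normal, sd 0.3, for the three abundances; a
truncated normal for the infected percentage): anchoring them directly to
the noisy, trended first samples injects a systematic transient that
visibly distorts parameter recovery.

## Priors

Rates and coefficients carry log-uniform priors over their plausible
decades (adsorption 1e-13–1e-9 L/day, clearance 1e-9–1e-5 L/day, quadratic
losses four decades each, burst size 1–500, lysis rate 0.5–6 /day,
effective GGE 1e-5–1e-1); amplitude and phase of division are uniform on
[0, 1]. The mean division rate is the exception: it carries an informative
log-normal prior (centre 0.55 /day, ln-sd 0.18, truncated to [0.1, 1.5])
by default. This is not a convenience: the likelihood pins the *product*
`mu_ave·delta_mu` (the oscillation amplitude of log cell counts) and is
nearly flat in `mu_ave` at fixed product — profile log-likelihood varies
by under one unit from 0.5 to 1.2 /day — so the mean turnover rate is
structurally unidentified from the four abundance signals alone. Division
of *Prochlorococcus* is, however, independently measurable (continuous
cell-size distributions from shipboard flow cytometry constrain it well),
and the prior represents that knowledge. `division_informed=False`
restores a flat prior; every prior is replaceable via `PriorSpec` or the
CLI config without code changes.

## Sampling

The sampler is a seeded ensemble MCMC (emcee) with differential-evolution
and snooker moves, held to the usual convergence contract: split R-hat and
bulk ESS per free parameter, R-hat < 1.05 to declare convergence.
Hamiltonian samplers make far better use of a step budget, so the
ensemble compensates with structure, all seeded and deterministic:

1. *Moment-matched starts.* The sin/cos harmonics of detrended log cell
   counts give the division amplitude product and phase by linear least
   squares; clearance, adsorption and the quadratic losses are then solved
   from the four stationary balance conditions at the observed mean
   abundances. Such starts sit on the coexistence manifold near a feasible
   fit.
2. *Stratified multistart optimisation.* Candidates are binned along the
   mean-division-rate axis (the softest global direction even under the
   informative prior) and the best of each bin is polished (Powell); the
   leaders are re-polished.
3. *Laplace-spread initialisation.* Walkers start around the best optima —
   near-tied optima are seeded in proportion to their posterior height —
   with covariance from the inverse Hessian at the mode, eigenvalues
   floored so that flat (ridge) directions stay wide. Short chains then
   report honest interval widths for weakly identified parameters.
4. *Pruning.* After warmup, walkers stranded more than 25 log-posterior
   units below the ensemble best are respawned near surviving walkers,
   followed by a half-length re-warmup before draws are collected.

At desk scale (tens of thousands of posterior evaluations) ridge-shaped
19-dimensional posteriors do not reach R-hat < 1.05; such fits are
returned flagged `converged=False` rather than silently accepted, and the
recovery harness reports how many replicates converged. Identifiability is
heterogeneous by construction: division rate, phase, adsorption and
clearance are well constrained, while burst size and the quadratic
cell/virus loss coefficients stay diffuse — the data constrain their
combinations (e.g. `beta·eta` against the virion loss budget), not each
factor alone.

## Mortality partitioning and residence times

Proportions are averages of pointwise ratios over the sampling window
(grid points with zero total mortality are excluded with a warning), which
differs from the ratio of averages whenever composition varies over the
diel cycle; the two conventions are distinguished explicitly in tests. The
lysis:grazing ratio is likewise the time average of the pointwise ratio.
Residence times convert quadratic loss coefficients to intuitive units via
the time-averaged per-capita loss: `1/(m_G·mean G)` for grazers, and for
virions both `1/(m_V·mean V)` (quadratic only) and `1/(m_V·mean V +
phi·mean(S+I))` (including the adsorption sink) are reported, since the
attribution of adsorbed virions is a convention. Posterior uncertainty is
propagated by re-simulating each draw (with its own initial conditions)
over the empirical window and aggregating mean/median/95% intervals;
failed simulations are excluded with a logged count.

## Sensitivity analysis

Single-parameter sweeps scale one of the ten rate/trait parameters by
0.25x–4x (33 log-spaced multipliers by default, exact 1.0 midpoint), run
to stationarity (1000-day burn-in) and evaluate the partition on the
stationary day; extinct points are recorded and masked, never raised. The
adsorption x clearance grid does the same on a factorial grid. Arc
classification takes central-difference elasticities of daily mortality
and the lysis:grazing ratio at multiplier 1 and groups parameters: growth
arc (a positive mortality response dominating the ratio response by at
least a factor of two — losses rise without their composition shifting
substantively), viral arc (ratio up), grazer arc (ratio down), and
insensitive (both elasticities inside a 0.1 deadband — e.g. the division
phase, which only shifts timing). The dominance factor and deadband are
implementer choices. Whether a fitted baseline uses posterior medians or a
single draw is configurable; medians are the default.

## Scales used in tests

The test suite runs the full 1000-day burn-ins for stationarity,
extinction and arc checks (the jitted engine makes these cheap), 9-point
sweep grids for arc signs, and five-replicate recovery experiments on
12-day low-noise cruises at 1-h/4-h cadence with 48-walker, 500+500-step
chains — sizes chosen so the whole suite runs on a single core in well
under half an hour while still exercising every stage end to end. The
cross-variant comparison harness is exercised across all six generalism
levels with reduced sampler budgets; full-scale posterior comparison of
the six variants on field data is an offline computation of hours and is
out of scope here.

## Known limitations

- No size structure, cell-cycle stages, nutrient dependence, mixotrophy or
  strain diversity; division forcing is a single sinusoid.
- The likelihood assumes independent Gaussian residuals after detrending;
  field data are autocorrelated and heteroscedastic.
- The ensemble sampler's convergence flag is honest but strict; published
  full-scale fits would need longer chains or gradient-based samplers.
- Residence-time conventions (quadratic-only vs total virion loss) differ
  by the adsorption sink; both are reported rather than adjudicated.
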