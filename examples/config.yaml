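# Example pipeline config for the `eclip` command.
#
# Every section is optional; omitted sections fall back to the documented
# library defaults.  Keys mirror the dataclass field names exactly, so the
# published values for priors, noise model or trend family can be dropped
# in without code changes.

params:                       # LifeHistoryParams (all rates per day, volumes in L)
  mu_ave: 0.5                 # mean division rate
  delta_mu: 0.8               # diel division amplitude (0..1)
  delta_t: 0.6                # division phase, days
  m_P: 2.2e-10                # quadratic cell loss, L/cell/day
  m_V: 4.5e-10                # quadratic virion loss, L/virion/day
  m_G: 6.0e-8                 # quadratic grazer loss, L/grazer/day
  phi: 3.8e-11                # adsorption rate, L/day
  psi: 4.4e-7                 # clearance rate, L/day
  beta: 150.0                 # burst size, virions/cell
  eta: 2.0                    # lysis rate (1/latent period)
  e_eff: 1.35e-3              # effective gross growth efficiency
  gamma: 0.0                  # generalist grazer gain (0 = specialist)

init:                         # state at t = 0 (06:00 local), per litre
  S: 9.85e7
  I: 1.5e6
  V: 1.0e9
  G: 1.0e6

# forcing:                    # uncomment for the diel-adsorption variant
#   diel_adsorption: true
#   low_factor: 0.5
#   high_factor: 1.5

simulate:
  t_end: 12.0
  method: RK45                # or "fixed" (jitted RK4)
  steps_per_day: 240

generator:                    # synthetic-cruise structure
  duration: 12.0
  pro_cadence_min: 60         # cell counts; down to 3 for cytometer cadence
  other_cadence_h: 4          # infected %, viruses, grazers

gammas: [0.0, 0.05, 0.5]      # variants fitted by `eclip fit`

mcmc:
  n_walkers: 48
  n_warmup: 500
  n_samples: 500

# noise:                      # likelihood noise treatment
#   mode: infer               # infer | fixed | marginal

# priors:                     # override any free prior, e.g.:
#   free:
#     eta: {dist: log-uniform, lo: 2.0, hi: 6.0}
#   fixed: {gamma: 0.0}

sensitivity:
  n_multipliers: 9
  burn_in: 1000
  parameters: [mu_ave, phi, psi, beta]
  pair_grid: false
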