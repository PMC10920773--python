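# eclip

Multitrophic population dynamics of *Prochlorococcus*, its T4/T7-like
cyanophage and heterotrophic nanoflagellate grazers under diel light
forcing — with Bayesian parameter inference, mortality partitioning and
parameter-sensitivity analysis.

## The scientific problem

*Prochlorococcus* dominates the photic zone of oligotrophic gyres such as
the North Pacific Subtropical Gyre, yet its abundance barely moves from
day to day: the cells' light-driven division is balanced almost exactly by
losses. Who takes the cells — viruses (lysis, which keeps matter in the
microbial loop) or grazers (which move it up the food web) — cannot be
read off abundances directly. This package fits a mechanistic community
model to multi-signal time series and asks the data which loss pathway
dominates, and with what uncertainty.

The model tracks susceptible cells S, infected cells I, free virions V and
grazers G (all per litre):

    dS/dt = mu(t) S − m_P S(S+I) − phi S V − psi S G
    dI/dt = phi S V − m_P I(S+I) − eta I − psi I G
    dV/dt = beta eta I − phi (S+I) V − m_V V^2
    dG/dt = e_eff psi (S+I) G + gamma G − m_G G^2

with diel division forcing `mu(t) = mu_ave (1 + delta_mu sin(2 pi (t +
delta_t)))` (t in days, t = 0 at 06:00 local). `gamma` sets the grazer's
diet breadth: 0 is a pure *Prochlorococcus* specialist; 0.01–0.5 /day give
increasingly generalist grazers. A model variant lets the adsorption rate
step between 0.5·phi (midnight–noon) and 1.5·phi (noon–midnight),
preserving its daily mean.

Total cell mortality decomposes as

    m_total = m_lysis + m_grazing + m_other
            = eta I  +  psi (S+I) G  +  m_P (S+I)^2

and the reported proportions are the time averages of the pointwise ratios
over the sampling window.

## Worked example

```python
from eclip import (DEFAULT_TRUE_PARAMS, DEFAULT_INIT, integrate,
                   partition, residence_times)

params = DEFAULT_TRUE_PARAMS          # cruise-like coexistence defaults
traj = integrate(params, DEFAULT_INIT, (0.0, 12.0), method="fixed",
                 steps_per_day=96)
part = partition(traj, params)
rt = residence_times(params, traj)
print(f"grazing {100*part.f_grazing:.1f}%  lysis {100*part.f_lysis:.1f}%  "
      f"other {100*part.f_other:.1f}%")
print(f"grazer residence {rt.grazer_residence:.1f} d, "
      f"virus residence {rt.virus_residence:.1f} d")
```

prints

```
grazing 89.4%  lysis 6.2%  other 4.4%
grazer residence 16.9 d, virus residence 2.2 d
```

— the field-like regime the defaults emulate: grazing removes roughly an
order of magnitude more cells per day than viral lysis, grazers turn over
on a two-to-three-week timescale and free virions in about two days.

The `examples/` directory has one short script per capability: simulating
the stationary diel cycle, generating synthetic cruise observations,
fitting the posterior, partitioning mortality, and sweeping parameters
into growth/viral/grazer sensitivity arcs. The `eclip` command exposes the
same stages as a pipeline (`eclip synthesize/fit/partition/sensitivity
--config cfg.yaml --seed N --out dir`), writing a run manifest beside each
output.

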