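"""Generate a cruise-like synthetic observation set with known truth.

The generator emulates the structure of a 12-day field campaign: hourly
flow-cytometry counts of total cells, 4-hourly bottle samples of infected
fraction, free viruses and nanoflagellates, a slow linear trend per signal
and multiplicative lognormal noise.  Because the generating parameters are
known, these sets are the test bed for the inference stage.
"""

from eclip import GeneratorConfig, generate

obs, truth = generate(GeneratorConfig(), seed=42)

print(f"duration: {obs.duration:.0f} days")
for name in ("pro", "infected_pct", "virus", "grazer"):
    s = obs[name]
    print(f"{name:13s} {len(s):4d} samples, mean {s.values.mean():.3g}")
print(f"true division rate: {truth.params.mu_ave} /day, "
      f"clearance {truth.params.psi:.2e} L/day, "
      f"adsorption {truth.params.phi:.2e} L/day")
# obs.to_csv("observations.csv") round-trips through read_observations();
# the truth record scores any later inference against the generator.
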