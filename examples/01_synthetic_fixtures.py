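"""Generate a synthetic study region: four environmental layers + localities.

The generator emulates the global 1-km layers (elevation, temperature,
precipitation, land cover) with seeded random fields, then samples presence
records of a warm-lowland species from a niche-weighted mixture.
"""

from habsuit import NicheSpec, gen_env_rasters, gen_localities

rasters = gen_env_rasters(seed=1)
niche = NicheSpec()  # TMA 20-32 degC x ALT 0-1000 m, 75% in-niche
localities, truth = gen_localities(rasters, niche, seed=2)

for code, r in rasters.items():
    print(f"{code}: {r.shape[0]}x{r.shape[1]} cells, "
          f"range [{r.grid.min():.1f}, {r.grid.max():.1f}]")
print(f"\n{len(localities)} localities; {truth['n_in_niche']} drawn in-niche "
      f"(windows: {truth['niche_windows']})")
# The in-niche count is the seeded Binomial(n, weight) draw; the rest are
# background records spread uniformly over land.
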