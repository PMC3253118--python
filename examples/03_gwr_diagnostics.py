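"""Confirm the selected pair with geographically weighted regression.

GWR refits the model locally at every record with bisquare weights reaching
to the 10th nearest neighbour.  On spatially structured data it should beat
the global OLS fit: lower corrected AIC, higher R^2.
"""

from habsuit import (
    GWRConfig,
    LocalityTable,
    NicheSpec,
    build_attribute_table,
    fit_gwr,
    fit_ols,
    gen_env_rasters,
    gen_localities,
    presence_intensity_response,
    project_points,
)

rasters = gen_env_rasters(seed=1)
localities, _ = gen_localities(rasters, NicheSpec(), seed=2)
attr = build_attribute_table(localities, rasters)
points = project_points(LocalityTable(attr[["species", "lon", "lat", "record_id"]].copy()))
y = presence_intensity_response(points)

pair = ["ALT", "TMA"]
ols = fit_ols(attr[pair].astype(float), y)
gwr = fit_gwr(attr[pair].astype(float), y, points, GWRConfig(k_neighbors=10))

print(f"OLS : AIC={ols.aic:8.1f}  R2={ols.r2:.3f}  adj R2={ols.adj_r2:.3f}")
print(f"GWR : AICc={gwr.aicc:7.1f}  R2={gwr.r2:.3f}  adj R2={gwr.adj_r2:.3f}  "
      f"tr(S)={gwr.trace_S:.1f}")
for name, q in gwr.coefficient_summary().items():
    print(f"  local beta[{name}]: median {q[0.5]:+.4f}  IQR [{q[0.25]:+.4f}, {q[0.75]:+.4f}]")
# A lower AICc and higher R^2 for GWR show the parameter effects vary in
# space; the local-coefficient spread says where each parameter matters.
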