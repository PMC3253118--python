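"""Check that model residuals are spatially random with Global Moran's I.

A trustworthy regression leaves no spatial pattern in its residuals:
Moran's I should be near its null expectation -1/(n-1), and the pattern
label should come out "random".
"""

import numpy as np

from habsuit import (
    GWRConfig,
    LocalityTable,
    NicheSpec,
    build_attribute_table,
    build_weights,
    fit_gwr,
    gen_env_rasters,
    gen_localities,
    morans_i,
    presence_intensity_response,
    project_points,
)
from habsuit.geodata import ProjectedPoints

rasters = gen_env_rasters(seed=1)
localities, _ = gen_localities(rasters, NicheSpec(), seed=2)
attr = build_attribute_table(localities, rasters)
points = project_points(LocalityTable(attr[["species", "lon", "lat", "record_id"]].copy()))
y = presence_intensity_response(points)
gwr = fit_gwr(attr[["ALT", "TMA"]].astype(float), y, points, GWRConfig(10))

# collapse duplicate coordinates to unique features (mean residual each)
coords = np.round(points.xy, 6)
uniq, inv = np.unique(coords, axis=0, return_inverse=True)
resid = np.zeros(len(uniq))
np.add.at(resid, inv, gwr.residuals)
resid /= np.bincount(inv)
pts_u = ProjectedPoints(x=uniq[:, 0], y=uniq[:, 1])

res = morans_i(resid, build_weights(pts_u))
print(f"n features      : {res.n}")
print(f"Moran's I       : {res.I:+.6f}")
print(f"expected E[I]   : {res.expected:+.6f}")
print(f"variance        : {res.variance:.6f}")
print(f"z-score / p     : {res.z:+.3f} / {res.p_value:.4f}")
print(f"pattern         : {res.pattern}")
# I close to E[I] with |z| < 1.96 means the residuals carry no spatial
# signal the model failed to absorb.
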