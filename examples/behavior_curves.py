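"""Response surfaces, ensemble curves and xylem vulnerability summaries.

Evaluates the forward model over a (soil water potential x scaled VPD)
grid, builds mean +/- SD response curves across the 43 published
per-observation parameter sets, and locates the tension at which mean
soil-to-leaf conductance halves.
"""

import numpy as np

from hydrostoma import GROUP_PARAMS
from hydrostoma.behavior import ensemble_curves, response_surface, vulnerability_curve
from hydrostoma.params import observation_params

# response surface for the subshrub group
psi_axis = np.linspace(-3.0, -0.033, 40)
D_axis = np.linspace(0.0035, 0.05, 30)
grid = response_surface(GROUP_PARAMS["SUBS"], psi_axis, D_axis, label="SUBS")
print("SUBS response surface:",
      f"g_s spans {grid.g_s_matrix.min():.2f}..{grid.g_s_matrix.max():.2f} mol m-2 s-1",
      f"over psi {psi_axis[0]}..{psi_axis[-1]} MPa and D {D_axis[0]}..{D_axis[-1]}")

# ensemble response to soil drying across published observation fits
axis = np.linspace(-4.0, -0.05, 50)
for pft in ("DCDS", "LEGM", "SUBS"):
    sets = list(observation_params(pft).values())
    curve = ensemble_curves(sets, axis, sweep="psi", fixed=0.03)
    wet = curve["mean"].iloc[-1]
    print(f"{pft}: mean g_s at -0.05 MPa = {wet:.2f} "
          f"(+/- {curve['sd'].iloc[-1]:.2f} across {len(sets)} observations)")

# vulnerability: where does mean soil-to-leaf conductance halve?
print("\nxylem tension halving the mean soil-to-leaf conductance:")
for pft in ("SUBS", "LEGM", "DCDS"):
    sets = list(observation_params(pft).values())
    _, half = vulnerability_curve(sets, np.linspace(-40, 0, 200))
    print(f"  {pft}: {half:.1f} MPa")
print("\nGroups with larger maximum conductance lose conductance faster "
      "under tension -- the efficiency-safety tradeoff.")
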