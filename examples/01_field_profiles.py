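"""Cross-stream velocity, temperature and shear profiles at one station.

Builds the default configuration, evaluates the closed-form fields at the
channel inlet (x = 0, where h = 1), and prints a short profile table.
"""

import numpy as np

from peristalsis_mhd import DimensionlessParams, StationSolution

params = DimensionlessParams()  # eps=0.5, M=2, beta=pi/6, alpha=pi/4, ...
dpdx = 0.0                      # zero imposed gradient: body-force-driven motion
st = StationSolution(x=0.0, dpdx=dpdx, params=params)

print(f"station x=0, h={st.h}, dp/dx={dpdx}")
print(f"{'y':>6} {'u':>10} {'theta':>10} {'S_xy':>10}")
for y in np.linspace(0.0, st.h, 9):
    print(f"{y:6.3f} {st.u(y):10.5f} {st.theta(y):10.5f} {st.shear(y):10.5f}")

print()
print("u runs from 0 at the centreline to -1 at the wall (the wall moves at")
print("-1 in the wave frame); theta from 0 to 1; S_xy is the Jeffrey shear")
print("stress (du/dy)/(1+lambda1). Viscous heating plus the heat source make")
print("theta bow above the straight conduction profile.")
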