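"""Coarse phase diagram of the two-resource model in the (r1, r2) plane.

Classifies the attractor reached from three initial conditions on an 8x8
grid.  The favorable start (everyone defects in resource 1) reaches the
periodic orbit earliest, the unfavorable start (defectors spread evenly)
latest; between those onsets both the defective fixed point and the orbit
are stable and the initial condition decides (bistability).
"""

import numpy as np

from pggchoice import Attractor, GameEnsemble, MutationRates, phase_diagram
from pggchoice.io import plot_phase_diagram, write_phase_diagram

grid = np.linspace(2.0, 9.0, 8)
ens = GameEnsemble(n=2, r=(4.4, 2.8), g=10)
diagram = phase_diagram(grid, grid, ens, MutationRates.symmetric(1e-3), T=2000)

for protocol in diagram.protocols:
    print(f"{protocol:12s} orbit onset r1 per r2 row:", diagram.po_onset(protocol))

fav = diagram.labels["favorable"]
unf = diagram.labels["unfavorable"]
bistable = (fav == Attractor.PERIODIC_ORBIT.value) & (unf == Attractor.DEFECTIVE_FP.value)
print(f"bistable cells (orbit from favorable, defective FP from unfavorable): "
      f"{bistable.sum()} of {grid.size ** 2}")

write_phase_diagram(diagram, "phase_diagram.csv", "boundaries.json")
plot_phase_diagram(diagram, "homogeneous", "phase_diagram.png")
print("wrote phase_diagram.csv, boundaries.json, phase_diagram.png")
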