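"""Cyclic dominance of cooperators and defectors at the canonical point.

Runs the exact replicator-mutator map and the agent-based simulator at
g = 10, r = (4.4, 2.8), nu = 1e-3 and compares their long-run cooperation
levels.  In this regime cooperators are not driven extinct: the population
cycles — cooperators build up one resource, defectors invade it, cooperators
shelter in the other resource, and so on.
"""

import numpy as np

from pggchoice import (
    GameEnsemble, MutationRates, classify_attractor, cooperation_level,
    initial_condition, iterate, simulate,
)

ens = GameEnsemble(n=2, r=(4.4, 2.8), g=10)
rates = MutationRates.symmetric(1e-3)
init = initial_condition("homogeneous", 2)

traj = iterate(init, 4000, ens, rates)
report = classify_attractor(traj)
rep_mean = cooperation_level(traj, window=(2000, 4000))
print(f"replicator: {report.label.value}, amplitude={report.amplitude:.3f}, "
      f"mean rho_C over t=2000..4000 = {rep_mean:.3f}")

abm = simulate(init.rho, ens, rates, T=5000, seed=1, N=10000)
abm_mean = cooperation_level(abm, window=(1000, 5000))
print(f"ABM (N=10000): mean rho_C over the last 4000 generations = {abm_mean:.3f}")
print(f"gap |ABM - replicator| = {abs(abm_mean - rep_mean):.3f}")

tail = traj.rho_C[2000:]
print(f"the orbit swings rho_C between {tail.min():.3f} and {tail.max():.3f}: "
      "cooperators repeatedly dominate and recede instead of dying out")
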