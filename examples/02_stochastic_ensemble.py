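"""Stochastic single-cell ensembles versus the mean-field ODE.

Simulates 1000 cells per gene archetype with the direct Gillespie algorithm
under constant 10 ng/ml stimulation and compares the ensemble with the
deterministic solution: the ensemble mean tracks the ODE, while the
cell-to-cell variability differs sharply between archetypes — the
slow-opening gene (CXCL10-like) is strongly heterogeneous and keeps a
nonresponding subpopulation, the fast gene (IRF1-like) does not.
"""

import numpy as np

from chromopulse import StimulusProtocol, StochasticConfig, ensemble, integrate, preset
from chromopulse.features import cv_over_time

proto = StimulusProtocol.constant(10.0)
print(f"{'gene':>7s} {'peak-P mean':>11s} {'peak-M mean':>11s} {'CV @ peak':>9s} "
      f"{'nonresp %':>9s} {'max |mean-ODE|/SEM':>18s}")
for gene in ("IRF1", "CXCL10", "CXCL9"):
    kin, adapt = preset(gene)
    res = ensemble(kin, adapt, proto, StochasticConfig(n_cells=1000, seed=1))
    P = res.species("P").astype(float)
    traj = integrate(kin, adapt, proto, res.time)
    sem = np.maximum(res.sem("P"), np.sqrt(np.maximum(traj["P"], 0) / 1000))
    z = np.max(np.abs(P.mean(axis=0) - traj["P"])[res.time >= 0] / sem[res.time >= 0])
    cv = cv_over_time(P)[P.mean(axis=0).argmax()]
    nonresp = 100 * np.mean(P.max(axis=1) < 5)
    print(f"{gene:>7s} {P.max(axis=1).mean():11.1f} "
          f"{res.species('M').max(axis=1).mean():11.2f} {cv:9.2f} {nonresp:9.1f} {z:18.2f}")

print(
    "\nSingle-cell peaks average ~40 protein and ~4 mRNA molecules (the"
    "\nreference count scaling); the last column shows the ensemble mean stays"
    "\nwithin a few standard errors of the deterministic solution."
)
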