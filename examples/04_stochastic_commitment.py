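"""Stochastic commitment of hfixL-knockout cells across the bistable window.

Simulates a Langevin ensemble of cells starting on the low-expression
branch at each O2 level inside the knockout's bistable window and
prints the fraction that commit to the high-expression state — the
model's account of the gradual, patchy fixNOQP onset seen in knockout
nodules.
"""

import numpy as np

from oxcascade import default_parameters
from oxcascade.io import default_noise_sigma
from oxcascade.model import Genotype
from oxcascade.steady import default_oxygen_grid, detect_bistable_window, sweep_bifurcation
from oxcascade.stochastic import commitment_fraction

params = default_parameters()
ko = Genotype.delta_hfixl()

branch = sweep_bifurcation(default_oxygen_grid(params, 60), params, ko, seed=0, n_starts=20)
window = detect_bistable_window(branch, seed=0)
print(f"bistable window: {window.lower * 1e9:.1f} - {window.upper * 1e9:.1f} nM dissolved O2")

pad = (window.upper / window.lower) ** 0.05
grid = np.geomspace(window.upper * pad, window.lower / pad, 8)
result = commitment_fraction(
    grid, params, ko, sigma=default_noise_sigma(), n_cells=200, seed=0
)
print(f"noise amplitude sigma = {result.sigma}, {result.n_cells} cells per point\n")
print("dissolved O2 (nM)   committed fraction")
for c, f in zip(result.dissolved_grid, result.fraction_high):
    print(f"{c * 1e9:>14.1f}      {f:.3f}")

print(
    "\nAs O2 drops through the window the low basin becomes shallower and a\n"
    "growing fraction of cells hops to high fnrN/fixNOQP expression —\n"
    "stochastic, cell-by-cell commitment, in contrast to the wild type\n"
    "where a single branch carries every cell up deterministically."
)
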