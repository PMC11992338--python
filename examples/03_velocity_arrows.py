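"""Overlay velocity-derived differentiation potential as grid arrows.

The transition graph sends each progenitor's edge mass mostly toward T1
(mixture 0.6/0.2/0.2).  Each cell's fate potential is its mean edge weight
into each terminal cluster; cells are binned into 10x10 grids on the
triangle and each occupied grid's normalized weights become arrows toward
the vertices.  Progenitor-rich grids should point mostly at T1.
"""

import numpy as np

import fatesimplex as fs

matrix, annotation, graph, _ = fs.generate(
    fs.FixtureSpec(seed=2, progenitor_mixture=[0.6, 0.2, 0.2]))
result = fs.compute_simplex(matrix, annotation,
                            fs.SimplexSpec(["T1", "T2", "T3"]), graph=graph)

field = result.field
print(f"{len(field.grids)} occupied grids covering "
      f"{field.n_cells_total} cells")
prog = annotation.indices_of("Progenitor")
prog_potential = result.potential.values[prog].mean(axis=0)
print("mean progenitor fate potential (T1, T2, T3):",
      "  ".join(f"{v:.4f}" for v in prog_potential))

arrows = fs.arrows(field, max_len=0.15)
print(f"{len(arrows)} arrows; per-grid lengths sum to 0.15")
fs.plot_ternary(result.coordinates, annotation, field=field,
                path="scratch_velocity.png")
print("wrote scratch_velocity.png")
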