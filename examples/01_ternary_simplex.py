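"""Place cells of a synthetic three-fate dataset inside a ternary simplex.

Builds a dataset with three terminal clusters (T1-T3) plus multipotent
progenitors, computes barycentric coordinates from the top Wilcoxon
markers, and prints where each population lands.  Terminal cells should
commit to their own vertex (own-fate affinity near 1); progenitors drawn
from a uniform mixture should sit near the center (1/3, 1/3, 1/3).
"""

import numpy as np

import fatesimplex as fs

matrix, annotation, graph, truth = fs.generate(fs.FixtureSpec(seed=1))
result = fs.compute_simplex(matrix, annotation,
                            fs.SimplexSpec(["T1", "T2", "T3"]))

labels = np.asarray(annotation.clusters)
print("mean barycentric coordinate per population (columns: T1, T2, T3):")
for pop in ["T1", "T2", "T3", "Progenitor"]:
    mean = result.coordinates.values[labels == pop].mean(axis=0)
    print(f"  {pop:<11s} " + "  ".join(f"{v:.3f}" for v in mean))

geom = fs.plot_ternary(result.coordinates, annotation,
                       path="scratch_ternary.png")
print(f"wrote scratch_ternary.png with {geom.points.shape[0]} cells")
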