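"""A four-fate (tetrahedron) simplex, using the PCA feature space.

With four terminal clusters the simplex is a regular tetrahedron rendered
in 3D.  Instead of Wilcoxon markers, cells are embedded on the top 10
principal components before distances are computed.
"""

import numpy as np

import fatesimplex as fs

matrix, annotation, _, _ = fs.generate(
    fs.FixtureSpec(seed=3, n_terminal_clusters=4))
result = fs.compute_simplex(matrix, annotation,
                            fs.SimplexSpec(["T1", "T2", "T3", "T4"]),
                            method="pca", n_components=10)

labels = np.asarray(annotation.clusters)
print("own-vertex argmax rate per terminal cluster (PCA space):")
for i, pop in enumerate(["T1", "T2", "T3", "T4"]):
    vals = result.coordinates.values[labels == pop]
    print(f"  {pop}: {(vals.argmax(axis=1) == i).mean():.2f}")

fs.plot_quaternary(result.coordinates, annotation,
                   path="scratch_quaternary.png",
                   view_angles=[(30, 20), (120, 15)])
print("wrote scratch_quaternary_view0.png / _view1.png")
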