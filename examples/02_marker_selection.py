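"""Select marker genes for each terminal fate by Wilcoxon rank-sum test.

Each terminal cluster is tested one-vs-rest-of-terminals per gene; the top
30 genes with positive log2 fold change are its markers.  On this fixture
the planted marker blocks (gene00000-09 for T1, etc.) should dominate the
selection.
"""

import fatesimplex as fs

matrix, annotation, _, truth = fs.generate(fs.FixtureSpec(seed=1))
normalized = fs.normalize_counts(matrix)
table = fs.wilcoxon_markers(normalized, annotation,
                            fs.SimplexSpec(["T1", "T2", "T3"]), top_k=30)

for fate in ["T1", "T2", "T3"]:
    selected = table.selected(fate)
    planted = set(truth["marker_blocks"][fate])
    hits = sum(1 for g in selected[:10] if g in planted)
    print(f"{fate}: top 3 markers {selected[:3]}; "
          f"{hits}/10 of the top 10 are planted markers")
print(f"shared feature subspace size: {len(table.feature_union)}")
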