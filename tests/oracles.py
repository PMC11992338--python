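"""Independent scalar oracles shared by unit and acceptance tests."""

import math


def scalar_chain(cells, centroids, sigma=0.08):
    """Straight-line scalar re-statement of the coordinate chain, used as an
    independent oracle: plain Python loops, no shared code with the package."""
    n_cells = len(cells)
    n_vert = len(centroids)
    d = [[math.sqrt(sum((cells[c][i] - centroids[v][i]) ** 2
                        for i in range(len(cells[0]))))
          for v in range(n_vert)] for c in range(n_cells)]
    d = [[d[c][v] / sum(d[c]) for v in range(n_vert)] for c in range(n_cells)]
    s = [[math.exp(-d[c][v] / sigma) for v in range(n_vert)]
         for c in range(n_cells)]
    scaled = []
    for c in range(n_cells):
        scaled.append([])
        for v in range(n_vert):
            col = [s[r][v] for r in range(n_cells)]
            scaled[c].append((s[c][v] - min(col)) / (max(col) - min(col)))
    return [[scaled[c][v] / sum(scaled[c]) for v in range(n_vert)]
            for c in range(n_cells)]
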