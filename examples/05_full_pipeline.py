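"""The one-shot pipeline: files in, TSV tables + plot + manifest out.

Writes a fixture to disk in the standard formats (MatrixMarket matrix with
sibling TSVs, annotation CSV, transition .mtx), then runs the whole
pipeline from a RunConfig.  The manifest alone reproduces the run
byte-for-byte.
"""

import json
import tempfile
from pathlib import Path

import fatesimplex as fs

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    fs.write_fixture(fs.FixtureSpec(seed=4), tmp / "inputs")

    out = fs.run(fs.RunConfig(
        matrix=str(tmp / "inputs" / "matrix"),
        annotation=str(tmp / "inputs" / "annotation.csv"),
        graph=str(tmp / "inputs" / "transition.mtx"),
        terminals=["T1", "T2", "T3"],
        out_dir=str(tmp / "run"),
        seed=4))

    print("outputs:", sorted(p.name for p in out.iterdir()))
    manifest = json.loads((out / "manifest.json").read_text())
    print(f"manifest: version={manifest['version']}, top_k={manifest['top_k']}, "
          f"sigma={manifest['sigma']}, resolution={manifest['resolution']}")
    head = (out / "coordinates.tsv").read_text().splitlines()[:3]
    print("coordinates.tsv head:")
    for line in head:
        print("  " + line)
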