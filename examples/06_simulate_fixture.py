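"""Emit a complete synthetic fixture directory of plain files.

The directory contains everything a real study would: per-element CSV
grids, the H&E-style WSI rendering (PNG), QuPath-dialect GeoJSON
annotations, a landmark CSV, and a truth JSON with the ground-truth
transform — enough to run the whole pipeline (or the CLI) end to end
with no patient data.
"""

import json
import tempfile
from pathlib import Path

from metalmap import FixtureSpec, make_fixture
from metalmap.simulate import write_fixture_dir

out = Path(tempfile.mkdtemp()) / "fixture"
fix = make_fixture(FixtureSpec(seed=0, landmark_noise_um=1.0))
paths = write_fixture_dir(fix, out)

for key, val in paths.items():
    if key != "channel_files":
        print(f"{key:12s} {val}")
truth = json.loads(Path(paths["truth"]).read_text())
print(f"elements: {truth['elements']}")
print(f"true transform model: {truth['true_transform']['model']}")
print(f"WSI raster: {fix.wsi.pixels.shape} at {fix.wsi.pixel_size_um} um/px; "
      f"elemental map: {fix.emap.shape} at {fix.emap.pixel_size_um} um/px")
# The same chain is available from the shell:
#   metalmap simulate --out-dir fixture --seed 0
#   metalmap convert fixture/channels/*.csv --out map.zarr --pixel-size-um 5
#   metalmap register fixture/landmarks.csv --out transform.json
#   metalmap transfer fixture/annotations.geojson transform.json map.zarr \
#       --out-dir transfer --wsi-pixel-size-um 0.25
#   metalmap stats map.zarr --label-table transfer/label_table.json --out summary.csv
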