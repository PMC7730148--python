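"""Generate a synthetic case library on disk and load it back.

Writes per-case gaze CSVs (t_ms, x_px, y_px, valid), the ROI polygon
file, a case manifest and a ground-truth sidecar with the planted token
sequences, then reloads everything through the manifest interface.
"""

import json
import tempfile
from pathlib import Path

from gazemine import generate_library, generate_roi_layout
from gazemine.io import load_manifest, read_gaze_csv
from gazemine.synthetic import planted_contrast_profiles

layout = generate_roi_layout(8, overlap_fraction=0.25, seed=1)
profiles = planted_contrast_profiles(layout)

out = Path(tempfile.mkdtemp()) / "library"
generate_library(profiles, layout, cases_per_group=3, seed=11, out_dir=out)
print("files written:", sorted(p.name for p in out.iterdir())[:6], "...")

entries = load_manifest(out / "manifest.json")
print(f"manifest lists {len(entries)} cases")
meta, gaze_path, roi_path = entries[0]
samples = read_gaze_csv(gaze_path)
print(f"{meta.case_id}: group={meta.group_id}, task={meta.task_id}, "
      f"{len(samples)} samples, {samples['valid'].mean():.1%} valid")

truth = json.loads((out / "ground_truth.json").read_text())
print("planted sequences in case 0:", truth[meta.case_id])
# The same files can be consumed by the CLI:
#   gazemine mine --manifest <library>/manifest.json --group-a expert --group-b novice ...
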