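"""From raw gaze samples to a fixation-ROI sequence and binned tokens.

Generates one synthetic 15 s / 60 Hz viewing session over an 8-ROI
layout, detects fixations with the velocity-threshold method (20 deg/s,
100 ms minimum dwell), assigns each fixation to an ROI and expands the
sequence into 150 ms dwell tokens.
"""

from gazemine import (
    CaseMeta,
    ScreenGeometry,
    bin_sequence,
    build_roi_sequence,
    detect_fixations,
    generate_roi_layout,
    generate_session,
)
from gazemine.synthetic import identical_strategy_profiles

layout = generate_roi_layout(8, overlap_fraction=0.25, seed=1)
profile = identical_strategy_profiles(layout)[0]
samples = generate_session(profile, layout, seed=3)
print(f"raw samples: {len(samples)} at 60 Hz ({samples['t_ms'].iloc[-1] / 1000:.1f} s)")

geom = ScreenGeometry()  # 27-inch display at 60 cm
fixations = detect_fixations(samples, geom, velocity_threshold=20.0, min_dwell=100.0)
print(f"fixations detected: {len(fixations)} "
      f"(mean dwell {sum(f.dwell for f in fixations) / len(fixations):.0f} ms)")

seq = build_roi_sequence(fixations, layout, CaseMeta(case_id="demo"))
print("fixation-ROI sequence:", " ".join(seq.labels))

binned = bin_sequence(seq, bin_window=150.0)
print(f"binned tokens ({len(binned.tokens)}):", " ".join(binned.tokens))
# Each fixation contributes ceil(dwell / 150 ms) repeated tokens, so the
# token sequence preserves both the visiting order and the dwell profile.
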