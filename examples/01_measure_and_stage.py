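"""Measure and stage a single annotated image.

Builds one synthetic CS4 annotation (15 named landmarks, reference markers
10 mm apart), derives the mm/pixel calibration, computes the five
morphometric measurements and assigns the CVM stage.
"""

import numpy as np

from cvmstage import compute_scale, measure, stage_record
from cvmstage.synthetic import sample_case

case = sample_case("CS4", np.random.default_rng(0), render=False)
record = case.record

scale = compute_scale(record)
ms = measure(record, scale)
result = stage_record(record)

print(f"calibration: {scale.mm_per_pixel:.4f} mm/pixel")
for name, value in ms.as_dict().items():
    print(f"  {name:10s} {value:.3f}")
print(f"stage: {result.stage}  (consistent pattern: {result.pattern_consistent})")
print(f"C3 shape: {result.c3_shape}, C4 shape: {result.c4_shape}")
# The three concavity depths (mm) and two base/height ratios drive the
# decision: all three borders concave + horizontal bodies -> CS4.
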