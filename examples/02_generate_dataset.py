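"""Generate a synthetic stage-conditioned dataset on disk.

Writes PNG images, LabelMe JSON annotations and a manifest CSV; the stage
split follows the default cohort frequencies unless explicit counts are
given.  Everything is reproducible from the seed.
"""

import tempfile
from pathlib import Path

from cvmstage.synthetic import generate_dataset

out = Path(tempfile.mkdtemp(prefix="cvm_synth_"))
cases, manifest = generate_dataset(30, seed=42, out_dir=out)

print(f"wrote {len(cases)} cases to {out}")
print(manifest["true_stage"].value_counts().sort_index().to_string())
print("files per case: image (.png), annotation (.json), plus manifest.csv")
# Each JSON is readable by read_labelme and stageable; the true stage is in
# the manifest and in the annotation's gold_stage flag.
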