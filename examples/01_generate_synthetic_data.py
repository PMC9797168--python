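"""Generate a small severity-graded synthetic fundus dataset.

Writes PNGs plus an APTOS-dialect train.csv (id_code,diagnosis) and prints
the class histogram and the oracle-visible lesion load per grade.
"""

import numpy as np

from gacnn import SyntheticSpec, generate_dataset

spec = SyntheticSpec(image_side=64, n_per_class=4, seed=42)
dataset = generate_dataset(spec, out_dir="scratch/example_data")

print("class histogram:", dataset.class_histogram())
for grade in spec.classes:
    imgs = [im for im, y in zip(dataset.images, dataset.labels) if y == grade]
    bright = np.mean([(im.astype(float).mean(2) / 255 > 0.85).sum()
                      for im in imgs])
    print(f"grade {grade}: mean bright-lesion area {bright:5.1f} px")
# The bright-lesion load rises sharply from grade 0 upward (with sampling
# noise at 4 images/grade); that monotone severity signal is what makes
# the 5-way classification learnable at desk scale.
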