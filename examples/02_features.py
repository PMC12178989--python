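"""The 54-value RGB grid descriptor of a bounding box.

A box is split into a 3x3 grid; each cell contributes the mean and standard
deviation of its R, G and B planes: 9 cells x 3 colours x 2 statistics = 54.
"""

import numpy as np

from trackreid import BoundingBox, extract_features
from trackreid.features import feature_names

# a patch that is pure red on the left half, pure blue on the right
img = np.zeros((30, 30, 3), dtype=np.uint8)
img[:, :15] = (255, 0, 0)
img[:, 15:] = (0, 0, 255)

v = extract_features(img, BoundingBox(6, 6, 18, 18))
print(f"descriptor length: {len(v)}")
for name, value in list(zip(feature_names(), v))[:8]:
    print(f"  {name:18s} = {value:7.2f}")
print("  ...")
print("left-column cells are pure red (R_mean 255, std 0); the middle column")
print("straddles the colour boundary, so its means sit between the colours")
print("and its standard deviations are large")
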