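"""A crop is a viewport, not a destruction — until the data is applied.

Crop a patch and then rotate it.  Eagerly, the rotation can only pull
padding into the corners because the crop already threw the surroundings
away.  Lazily, the crop is just a translation description, so the rotation
recovers real data from outside the window.
"""

import math

import numpy as np

from lazyresample import apply_all, crop_patch, make_meta_image, rotate

rng = np.random.default_rng(0)
img = make_meta_image(rng.random((1, 32, 32)).astype(np.float32) + 1.0)

angle = math.radians(30)
lazy_out = apply_all(rotate(crop_patch(img, (8, 8), (16, 16)), angle))
eager_out = rotate(crop_patch(img, (8, 8), (16, 16), lazy=False), angle, lazy=False)

# every input value is >= 1, so zeros can only come from padding
lazy_pad = int(np.sum(lazy_out.data == 0))
eager_pad = int(np.sum(eager_out.data == 0))
print(f"padding pixels, lazy crop+rotate  : {lazy_pad}")
print(f"padding pixels, eager crop+rotate : {eager_pad}")
print()
print("The eager pipeline destroyed everything outside the window, so the")
print("rotation fills the corners with padding; the lazy pipeline samples")
print("the original volume once, through the composed map, and recovers")
print("the data the crop had only *described* removing.")
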