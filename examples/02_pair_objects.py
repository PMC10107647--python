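"""Pair objects of interest between two images after registration.

Generates 30 "nuclei", rotates them into a second image, drops two of them
(as if the user forgot to label them), fits the rotation from 5 landmarks
and pairs the rest.  Dropped objects surface as multiply-assigned ids.
"""

import numpy as np

from lmreg3d import PointSet, fit_rotation, pair_objects, transform_points
from lmreg3d.synthetic import _random_rotation_angles

rng = np.random.default_rng(42)

objects1 = PointSet.from_coords(rng.uniform(0, 80, (30, 3)))
angles = _random_rotation_angles(rng)
objects2 = transform_points(objects1, angles, objects1.centroid, objects1.centroid)
objects2 = objects2.select(np.arange(2, 30))  # ids 1 and 2 were never labeled

lm_idx = np.array([4, 9, 14, 19, 24])  # indices into objects1 rows
fit = fit_rotation(objects1.select(lm_idx), objects2.select(lm_idx - 2)).best

table = pair_objects(objects1, fit.transform(objects2), k=3)
print(table.to_frame().head(6).to_string(index=False))
print(f"\nmultiply-assigned image-2 ids: {sorted(table.multiply_assigned)}")
print("(each image-1 row lists its 3 nearest image-2 candidates with distances"
      " in um; rank-1 distance ~0 means a confident pair, and the two unlabeled"
      " objects force some image-2 id to be claimed twice)")
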