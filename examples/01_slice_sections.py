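"""Cut a synthetic brain atlas into a registered coronal section series.

Builds the default synthetic atlas, generates five evenly spaced coronal
cut planes, and extracts each section's atlas label map by nearest-voxel
sampling along the plane.
"""

import numpy as np

from histoatlas import SynthSpec, make_atlas, make_series, slice_atlas

atlas, hierarchy = make_atlas(SynthSpec(seed=1))
print(f"atlas {atlas.name}: {atlas.shape} voxels, "
      f"{len(hierarchy)} regions, midline axis {atlas.midline[0]} "
      f"at plane {atlas.midline[1]}")

series, images = make_series(atlas, n_sections=5, seed=2)
for section in series.sections:
    lm = slice_atlas(atlas, section.anchoring)
    regions = [int(r) for r in np.unique(lm) if r]
    tissue = int((lm > 0).sum())
    print(f"section {section.nr} ({section.filename}): "
          f"{tissue} tissue pixels, regions {regions}")

# Each line reports one cut plane: how many of its pixels land inside the
# brain and which atlas regions the plane intersects. Middle sections cross
# the subcortex and nuclei; outer sections only graze the cortex shell.
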