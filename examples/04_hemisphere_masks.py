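"""Split sections into hemispheres at the atlas midline plane.

Every pixel is mapped to atlas space and classified by its coordinate along
the midline axis; with warp markers the classification respects the
nonlinear deformation, so the mask boundary follows the warped midline.
"""

from histoatlas import (
    LEFT, RIGHT, SynthSpec, WarpMarker, hemisphere_mask, make_atlas, make_series,
)

atlas, _ = make_atlas(SynthSpec(seed=1))
series, _ = make_series(atlas, 5, seed=2)

for section in series.sections:
    hm = hemisphere_mask(atlas, section.anchoring)
    left, right = int((hm == LEFT).sum()), int((hm == RIGHT).sum())
    print(f"section {section.nr}: left={left} right={right} px "
          f"(imbalance {abs(left - right)})")

# a rightward drag at the center moves the apparent midline
a = series.sections[2].anchoring
cx, cy = (a.width - 1) / 2, (a.height - 1) / 2
warped = hemisphere_mask(atlas, a, [WarpMarker((cx + 4, cy), (cx, cy))])
left_w = int((warped == LEFT).sum())
print(f"with a 4 px rightward drag: left={left_w} px "
      f"(was {int((hemisphere_mask(atlas, a) == LEFT).sum())})")

# The synthetic atlas is mirror-symmetric and the sections are centered, so
# the unwarped masks split each image exactly in half; the warped mask gains
# left pixels because tissue right of the midline now samples left atlas
# coordinates.
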