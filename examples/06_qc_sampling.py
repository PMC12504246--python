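"""Assess registration accuracy and tissue damage by systematic sampling.

A regular grid is laid over a section; in-tissue points are rated accurate,
inaccurate, uncertain or damage (here by a simulated rater). Accuracy is
reported per reporting region, and sections exceeding a damage threshold
are flagged for exclusion.
"""

import numpy as np

from histoatlas import SynthSpec, collapse_hierarchy, make_atlas, make_series, slice_atlas
from histoatlas.qc import ACCURATE, DAMAGE, INACCURATE, generate_grid, qc_statistics

atlas, hierarchy = make_atlas(SynthSpec(seed=1))
series, _ = make_series(atlas, 5, seed=2)
mapping = collapse_hierarchy(hierarchy, {2, 3})  # report at hemisphere level
names = {n.id: n.name for n in hierarchy}

rng = np.random.default_rng(6)
for section in series.sections:
    lm = slice_atlas(atlas, section.anchoring)
    grid, assessment = generate_grid(section.width, section.height,
                                     spacing=6, label_map=lm)
    # simulated rater: 90% accurate, 5% inaccurate, 5% damage in tissue
    for i, label in enumerate(assessment):
        if label is None:
            assessment[i] = rng.choice(
                [ACCURATE, INACCURATE, DAMAGE], p=[0.9, 0.05, 0.05]
            )
    report, exclusion = qc_statistics(grid, assessment, lm, mapping,
                                      damage_threshold=0.1,
                                      section_nr=section.nr)
    acc = {names[rid]: f"{r.accuracy:.2f}" for rid, r in report.regions.items()
           if r.accuracy is not None}
    print(f"section {section.nr}: {report.in_tissue_points} in-tissue points, "
          f"damage {report.damage_fraction:.2f}, "
          f"excluded={exclusion['section_excluded']}, accuracy {acc}")

# Accuracy is accurate/(accurate+inaccurate) per hemisphere; the damage
# fraction is the share of in-tissue grid points marked damaged, and a
# section is excluded when it exceeds the 10% threshold.
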