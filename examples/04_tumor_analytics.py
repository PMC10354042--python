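"""Tumor-level analytics on a grade map: overall grades, heterogeneity, burden.

Works directly on a ground-truth label raster, so no trained model is needed.
"""

import numpy as np

from lunggrade import synthetic
from lunggrade.analysis import segment_tumors, size_distribution, slide_summary, tumor_table
from lunggrade.types import GradeMap

spec = synthetic.random_slide_spec(5, canvas_size=(384, 384), n_tumors=5)
_, labels = synthetic.make_synthetic_slide(spec)
grade_map = GradeMap(labels)

tumors = segment_tumors(grade_map, connectivity=8)
print(tumor_table(tumors).round(3).to_string(index=False))

summary = slide_summary(grade_map, tumors)
print(f"\nlung area {summary.lung_area_um2:,.0f} um^2, "
      f"tumor burden {summary.burden_fraction:.1%}")
dist = size_distribution(tumors)
print(f"{dist.min_tumors_for_half_area} largest tumor(s) hold half the tumor area")
# overall_grade follows the >=10% rule: the highest grade covering at least
# a tenth of the tumor; sdi is the Shannon diversity of its grade mosaic.
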