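"""Build a slide-disjoint, area-balanced patch library from annotated slides.

Tiles six synthetic slides into 64-px patches, groups them by dominant
class, splits 60/20/20 with each slide confined to one split, and balances
per-class pixel area by augmentation.
"""

from collections import Counter

from lunggrade import synthetic
from lunggrade.patches import LabelMask, balance_by_area, build_library

slides = []
for seed in range(6):
    rgb, labels = synthetic.make_synthetic_slide(
        synthetic.random_slide_spec(seed, canvas_size=(320, 320))
    )
    slides.append((rgb, LabelMask(labels)))

library = build_library(slides, quota_per_class=40, size=64, stride=64, seed=0)
print("patches per split:", dict(Counter(library.split)))
print("dominant classes:", dict(Counter(p.dominant_class.name for p in library.patches)))

balanced = balance_by_area(library, seed=0)
areas = balanced.class_area("train")
print("train-split class areas (px) after balancing:")
for cls, area in areas.items():
    print(f"  {cls.name:16s} {area}")
# Balanced areas let the network train with uniform class weights; every
# slide's patches stay inside a single split so evaluation is slide-held-out.
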