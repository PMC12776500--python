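"""Classify cells by marker regions and profile LMS against HZ distance.

The synthetic field marks the whole domain Col2-positive with a ColX-positive
hypertrophic-zone (HZ) strip at one edge, mimicking a growth plate.
Chondrocytes within 400 μm of the HZ become "chondro-PZ" (the proliferative-
zone proxy); the distance-binned profile shows how a score varies with
position along the growth plate.
"""

import numpy as np

from misalign import (
    FieldSpec,
    LmsConfig,
    assign_pz,
    bin_by_distance,
    classify_by_regions,
    distance_to_hz,
    generate_field,
    lms_scores,
)

cells, regions = generate_field(
    FieldSpec(n_cells=1200, width=600.0, height=1200.0,
              noise_model="wrapped_normal", sigma_deg=15.0, seed=2)
)
classify_by_regions(cells, regions)
distances = distance_to_hz(cells, regions)
assign_pz(cells, distances, window=(0.0, 400.0))

counts = {}
for c in cells:
    counts[c.class_label] = counts.get(c.class_label, 0) + 1
print("class counts:", dict(sorted(counts.items())))

scores = lms_scores(cells, LmsConfig(radius=40.0, classes=("chondrocyte", "chondro-PZ")))
profile = bin_by_distance(scores["lms_deg"], distances[scores.index], bin_width=200.0)
print("\ndistance bin (μm)   mean LMS   n cells")
for lo, hi, m, n in zip(profile.bin_edges[:-1], profile.bin_edges[1:],
                        profile.mean, profile.count):
    m_str = f"{m:7.2f}" if np.isfinite(m) else "      -"
    print(f"  [{lo:4.0f}, {hi:4.0f})     {m_str}    {n:5d}")

print(
    "\nCells in the ColX+ strip are chondro-hyper and are excluded from the\n"
    "chondrocyte LMS; the flat profile reflects a spatially uniform noise\n"
    "model (a graded mutant would rise with distance)."
)
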