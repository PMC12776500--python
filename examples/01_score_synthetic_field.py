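"""Score an aligned and a disorganized synthetic field with LMS and GOA.

Generates two fields of elliptical cells — one perfectly aligned with the
tissue axis, one with uniformly random axial orientations — and prints the
mean Local Misalignment Score (LMS, 0 = locally coherent, 45 = locally
random) and the spread of the Global Orientation Angle (GOA, deviation from
the proximal–distal axis) for each.
"""

from misalign import FieldSpec, LmsConfig, generate_field, goa_scores, lms_scores

for name, noise in (("aligned", "none"), ("random", "uniform")):
    spec = FieldSpec(
        n_cells=800,
        width=800.0,
        height=800.0,
        mean_orientation_deg=90.0,  # long axis along the 90° tissue axis
        noise_model=noise,
        axis_deg=90.0,
        seed=1,
    )
    cells, _ = generate_field(spec)
    lms = lms_scores(cells, LmsConfig(radius=60.0))
    axes = {spec.annotation_id: spec.axis_deg}
    goa = goa_scores(cells, axes)
    defined = lms["lms_deg"].dropna()
    print(
        f"{name:>8}: mean LMS = {defined.mean():5.2f} deg "
        f"({len(defined)} cells, {lms['neighbor_count'].mean():.1f} neighbors avg); "
        f"GOA IQR = [{goa.quantile(0.25):.1f}, {goa.quantile(0.75):.1f}] deg"
    )

print(
    "\nLow LMS means neighbors share an orientation; random neighborhoods\n"
    "push the mean toward the 45-degree ceiling (reaching it as neighborhoods\n"
    "grow large). A narrow GOA interquartile range means the population\n"
    "aligns with the tissue axis."
)
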