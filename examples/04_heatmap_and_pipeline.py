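"""Run the full pipeline on a synthetic cohort and render an LMS heatmap.

Generates a two-group cohort (orientation noise growing distally in the
mutant, as in a ligand-gradient loss), then runs read → classify → zone →
score → summarize → test → render in one call. Outputs land in
./example_output/: scores.csv, medians.csv, test.json, heatmap.png.
"""

from pathlib import Path

import pandas as pd

from misalign import CohortSpec, FieldSpec, generate_cohort, run_pipeline

out = Path("example_output")


def field(sigma):
    return FieldSpec(n_cells=250, width=450.0, height=450.0,
                     noise_model="wrapped_normal", sigma_deg=sigma)


elements = ["1", "2", "3", "4"]
spec = CohortSpec(
    groups={
        "wt": (3, {e: field(8.0) for e in elements}),
        "mut": (3, {e: field(8.0 + 8.0 * int(e)) for e in elements}),
    },
    seed=42,
)
manifest = generate_cohort(spec, out / "cohort")
results = run_pipeline(manifest, out / "run", {"radius_um": 40.0, "seed": 1})

medians = pd.read_csv(results["medians"], index_col=0)
print("median LMS per embryo × element (deg):")
print(medians.round(2).to_string())
print(
    f"\npermutation test: statistic = {results['result'].statistic:.2f}, "
    f"p = {results['result'].p_value:.4f}"
)
print(f"heatmap written to {results['heatmap']}")
print(
    "\nMutant embryos show element-graded LMS elevation (rows named mut-*\n"
    "rise from element 1 to 4) while wild-type rows stay flat — the spatial\n"
    "signature that distinguishes a graded ligand loss from a uniform defect."
)
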