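"""End-to-end high-content profiling on a small synthetic experiment.

Runs the full pipeline (simulate -> track -> 44-entry Z-score profiles ->
pooled profiles -> two-way-ANOVA comparisons) on 4 lines x 2 treatments with
the shipped scenario: a distal-only organelle-trafficking deficit in the
mutant pool that the 10 Hz setting rescues.
"""

from axoquant import ExperimentDesign, run_full_pipeline

design = ExperimentDesign(
    lines={"Ctrl1": "Ctrl", "Ctrl2": "Ctrl", "FUS1": "mutantFUS", "FUS2": "mutantFUS"},
    treatments=("untreated", "10Hz"),
    movies_per_condition=2,
    master_seed=7,
)
bundle = run_full_pipeline(design, out_dir="scratch/hc_demo", n_frames=40, frame_px=160)

print(f"movies analyzed: {bundle['manifest']['n_movies']}")
for name in ("Ctrl untreated", "mutantFUS untreated", "mutantFUS 10Hz"):
    prof = bundle["pooled"][name]
    distal = prof[prof.position == "distal"].z
    proximal = prof[prof.position == "proximal"].z
    print(f"{name:22s} mean Z distal {distal.mean():+.2f}   proximal {proximal.mean():+.2f}")
print("(untreated-control proximal entries are 0 by self-normalization; the mutant")
print(" pool shows a distal-only negative deviation that 10 Hz pulls back to ~0)")

print("\npairwise two-way-ANOVA comparisons (Bonferroni-adjusted):")
print(bundle["comparisons"].to_string(index=False))
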