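"""Quantify marker-positive percentages on a synthetic IF still.

Renders 200 cells with a 70.18% MAP2-positive fraction and a 78.5%
SMI32-positive fraction *within* the MAP2-positive population, then runs
nucleus segmentation and nucleus-anchored marker counting.
"""

from axoquant import IFSceneConfig, generate_if_image, quantify_if_image

cfg = IFSceneConfig(
    n_cells=200,
    markers=("MAP2", "SMI32"),
    positive_fraction={"MAP2": 0.7018, "SMI32": 0.785},
    conditional_on={"SMI32": "MAP2"},
    seed=11,
)
image, truth = generate_if_image(cfg)
q = quantify_if_image(image, conditional={"SMI32": "MAP2"})

true_map2 = 100 * truth.objects.MAP2_positive.mean()
true_cond = 100 * truth.objects.SMI32_positive[truth.objects.MAP2_positive].mean()
print(f"MAP2+ cells:            {q.percent_positive['MAP2']:.1f}%   (ground truth {true_map2:.1f}%)")
print(f"SMI32+ within MAP2+:    {q.percent_smi32_in_map2:.1f}%   (ground truth {true_cond:.1f}%)")
print("(percent of Hoechst-segmented nuclei whose dilated nuclear region exceeds")
print(" the blank-area + 3 SD marker threshold; the conditional percentage scores")
print(" motoneuron identity within the neuronal population)")
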