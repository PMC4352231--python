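"""Differential expression from a two-colour interwoven loop design.

Simulates the 2011 triangle (deltamethrin-selected VK7, unexposed VK7, and
the Mali susceptible colony; three dye-swapped arrays per comparison) with
planted expression differences, fits the per-probe loop model and prints
the strongest resistant-vs-susceptible fold changes.
"""

import pandas as pd

import resistkit as rk

truth = rk.make_expression_truth(n_probes=500, seed=0)
design = rk.vk_design_2011()
intens = rk.simulate_two_color_experiment(
    design, truth, noise_sd=0.25, dye_bias=0.1, array_effect_sd=0.2, seed=1
)
norm = rk.normalize(intens, method="median")
contrasts = rk.fit_contrasts(norm, design, [("VKR2011", "MAL2011")])

top = contrasts.nsmallest(5, "q").assign(FC=lambda d: 2.0 ** d["log2FC"])
print(top[["probe_id", "log2FC", "FC", "p", "q"]].to_string(index=False))
# log2FC is the fitted log2 ratio of selected VK7 over the susceptible
# colony; FC is the same on the natural scale, and q the BH-adjusted
# p-value used by the downstream candidate filters.
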