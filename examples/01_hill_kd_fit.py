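"""Fit the Ca2+ sensitivity (Hill Kd) of two thin-filament constructs.

Generates synthetic fluorescence titrations for a wild-type construct and
a Ca2+-sensitized variant (true Kd lowered 1.7-fold), fits each replicate
with the Hill equation, and compares the constructs with an unpaired
Student t test.
"""

from alternans import kinetics, synth

wt = synth.gen_titration(true_kd=3.4, n_replicates=8, seed=1, construct_label="WT")
variant = synth.gen_titration(
    true_kd=3.4 / 1.7, n_replicates=6, seed=2, construct_label="variant"
)

fit_wt = kinetics.fit_hill(wt)
fit_var = kinetics.fit_hill(variant)
comp = kinetics.compare_parameters(fit_wt.per_replicate_kd, fit_var.per_replicate_kd)

for fit in (fit_wt, fit_var):
    print(
        f"{fit.construct_label:8s} Kd = {fit.kd:.3f} +/- {fit.kd_sem:.3f} uM "
        f"(n = {len(fit.per_replicate_kd)}, Hill n = {fit.hill_n:.2f})"
    )
print(f"Kd ratio WT/variant = {comp.fold_ratio:.2f}  (p = {comp.p_value:.2e})")
print(
    "A ratio near 1.7 means the variant reaches half-maximal activation at a"
    " 1.7-fold lower Ca2+ concentration, i.e. it is Ca2+-sensitized."
)
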