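"""Analyze a semantic-differential survey comparing two explanations.

Simulates 16 experts rating 10 images per approach on eight bipolar
attributes, reduces ratings to subject medians, runs paired Wilcoxon
tests with Bonferroni correction, and reports bootstrap CIs and the
post-hoc power for large effects.
"""
from plantarqc.survey import (PowerSpec, bootstrap_median_ci,
                              paired_wilcoxon_bonferroni, posthoc_power,
                              simulate_ratings, subject_medians)

ratings = simulate_ratings(n_participants=16, n_items=10, seed=2,
                           shift={"simplicity": -1.0})
medians = subject_medians(ratings)
tests = paired_wilcoxon_bonferroni(medians)
print(tests.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

simp = medians[(medians["attribute"] == "simplicity")
               & (medians["approach"] == "B")]["median"].to_numpy()
lo, hi = bootstrap_median_ci(simp, seed=0)
print(f"approach B 'simplicity' median CI: [{lo:.2f}, {hi:.2f}]")
power = posthoc_power(PowerSpec(effect_size=0.8, n_pairs=16))
print(f"post-hoc power for dz=0.8, n=16: {power:.2f} — only large paired")
print("effects are detectable at this sample size.")
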