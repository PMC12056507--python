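"""Interobserver agreement statistics on a simulated rater panel.

Four simulated human raters (smooth boundary jitter around the true
spheroid) segment the same images; pairwise Jaccard distances per
image form a blocks × pairs table analysed with the Friedman rank
test and Dunn–Bonferroni pairwise post hoc comparisons.
"""

import numpy as np

import spheroidseg as ss

config = ss.synth.desk_scale_config(seed=3)
panel = {f"H{r + 2}": [] for r in range(4)}
for i in range(30):
    target = ss.generate_sample(config, i).target
    # raters differ in care: H2 jitters least, H5 most
    for r in range(4):
        amp = 1.0 + r * 1.0
        panel[f"H{r + 2}"].append(ss.perturb_as_rater(target, amp, seed=31 * i + r))

table = ss.interobserver_matrix(panel)
print(f"{table.shape[0]} images, {table.shape[1]} rater pairs: {list(table.columns)}")
print("mean pairwise JCD per pair:")
for col in table.columns:
    print(f"  {col}: {table[col].mean():.3f}")

stat, p = ss.friedman_test(table.to_numpy())
print(f"Friedman chi2 = {stat:.1f}, p = {p:.2e} "
      "(pairs involving the sloppier raters rank consistently worse)")

posthoc = ss.dunn_bonferroni(table.to_numpy(), list(table.columns))
sig = posthoc[posthoc.p_adjusted < 0.005]
print(f"{len(sig)}/{len(posthoc)} pair-of-pairs comparisons significant at p < 0.005")
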