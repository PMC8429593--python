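"""Reader-consensus validation of the noisy/correct triage.

Emulates the expert-reader design: an independent reader labels 100 items the
cleansing flagged as correct and 100 flagged as noisy (presented in
randomized order). On correct-labeled items the reader agrees far beyond
chance; on noisy items agreement is indistinguishable from chance —
Cohen's kappa quantifies both.
"""

import numpy as np

from udclean import randomize_reading_order, reader_study

rng = np.random.default_rng(0)

# Dataset labels of the two 100-image subsets (clean: 48/52 split, noisy: 51/49)
clean_labels = np.array([0] * 48 + [1] * 52)
noisy_labels = np.array([0] * 51 + [1] * 49)

# Simulated reader: 95% agreement on clean items, coin-flip on noisy items
clean_reader = np.where(rng.random(100) < 0.95, clean_labels, 1 - clean_labels)
noisy_reader = np.where(rng.random(100) < 0.50, noisy_labels, 1 - noisy_labels)

order = randomize_reading_order(np.arange(200), seed=0)  # fatigue-bias control
print(f"reading order randomized, first five presented: {order[:5]}")

report = reader_study(clean_labels, clean_reader, noisy_labels, noisy_reader)
kc, kn = report.kappa_clean, report.kappa_noisy
print(f"kappa(correct subset) = {kc.kappa:.2f}  (vs chance: p = {kc.p_value:.2g})")
print(f"kappa(noisy subset)   = {kn.kappa:.2f}  (vs chance: p = {kn.p_value:.2g})")
print(f"difference = {report.kappa_difference:.2f}, one-sided p = "
      f"{report.p_value_difference:.2g}")
# Agreement beyond chance on the correct subset but not on the noisy one
# indicates the noisy items genuinely lack label-relevant information.
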