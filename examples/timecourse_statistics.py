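"""Test per-animal positive-nuclei fractions against the mock group.

Simulates 9 animals per timepoint (200 scored nuclei each) with a
proliferation burst at 1-3 dpa, then computes group mean +/- SEM and
Bonferroni-adjusted Wilcoxon rank-sum p-values versus mock.
"""

import numpy as np
import pandas as pd

from hepaquant.imaging import timecourse_test

rng = np.random.default_rng(2)
rates = {"mock": 0.02, "0dpa": 0.03, "1dpa": 0.25, "2dpa": 0.40, "3dpa": 0.30}
rows = []
for tp, rate in rates.items():
    for i in range(9):
        frac = rng.binomial(200, rate) / 200
        rows.append({"animal": f"{tp}_{i}", "timepoint": tp, "fraction": frac})

result = timecourse_test(pd.DataFrame(rows), reference="mock")
print(result.round(4).to_string(index=False))
print()
print("Each row summarises one timepoint over 9 animals; p_adj is the")
print("rank-sum p versus mock, Bonferroni-corrected over the 4")
print("comparisons. The proliferation burst at 1-3 dpa is significant.")
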