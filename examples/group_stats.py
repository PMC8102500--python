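"""Group comparisons: one-way ANOVA with Holm-adjusted pairwise t tests.

Simulates a three-condition experiment (control, weak effect, strong
effect) and reports the tidy statistics table with the significance-star
convention *P < 0.05, **P < 0.01, ***P < 0.001.
"""

import numpy as np

import nequant as nq

rng = np.random.default_rng(11)
groups = {
    "control":   rng.normal(1.00, 0.15, 18),
    "condition A": rng.normal(1.10, 0.15, 18),
    "condition B": rng.normal(1.55, 0.15, 18),
}
result = nq.compare_groups(groups, design="anova_holm")
print(result[["test_name", "groups", "statistic", "p_raw", "p_adjusted", "stars"]]
      .to_string(index=False))
print()
print("The ANOVA row tests any difference among the three groups; each pairwise")
print("row is a Welch t test with its p-value Holm-adjusted for the 3 comparisons.")
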