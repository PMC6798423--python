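"""Compare the semi-parametric test with the two-part t and Wilcoxon tests.

Simulates one scenario-1 style dataset with a skewed non-zero source, runs
all three tests, and prints feature-ranking AUC on all features and on the
non-normal stratum (Shapiro-Wilk p < 0.01 in at least one group).
"""

import numpy as np

from sda import SimConfig, simulate_dataset, run_test, run_baselines
from sda.core import DesignMatrix
from sda.evaluate import auc, flag_nonnormal

mat, cov, truth = simulate_dataset(
    SimConfig(n_per_group=50, n_features=300, de_fraction=0.1,
              source="skewed", seed=21))
design = DesignMatrix(X=cov[["group"]].to_numpy(float), test_index=0)

sda_table = run_test(mat, design)
base_table = run_baselines(mat, design)

group1 = (cov["group"] == 1).to_numpy()
nonnormal = np.array([flag_nonnormal(row[~group1], row[group1])
                      for row in mat.to_numpy()])
print(f"{nonnormal.mean():.0%} of features flagged non-normal\n")

print(f"{'method':<6} {'AUC(all)':>9} {'AUC(non-normal)':>16}")
for name, pvals in [("SDA", sda_table["pvalue"]),
                    ("2T", base_table["2t_pvalue"]),
                    ("2W", base_table["2w_pvalue"])]:
    p = pvals.to_numpy()
    ok = np.isfinite(p)
    m = ok & nonnormal
    print(f"{name:<6} {auc(-p[ok], truth.is_de[ok]):>9.3f} "
          f"{auc(-p[m], truth.is_de[m]):>16.3f}")
print()
print("AUC is the probability a truly differential feature ranks above a")
print("null one; the distribution-free non-zero model pays off most on the")
print("non-normal stratum.")
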