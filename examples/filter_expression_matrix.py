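"""Univariate pre-filtering of a (synthetic) expression matrix.

RNA-seq analyses usually drop genes that are neither variable nor expressed
before any model fitting.  The rule here keeps a gene if its coefficient of
variation is at least 5 OR its mean log2 expression is at least 3.
"""

import numpy as np
import pandas as pd

import robitsel as rs

rng = np.random.default_rng(0)
n = 60
mat = pd.DataFrame({
    # highly expressed housekeeping-like gene: high mean, low CV
    "HK1": rng.normal(8.0, 0.5, n),
    # lowly expressed but bursty gene: low mean, high CV
    "BURSTY1": np.abs(rng.standard_normal(n)) * 0.02 + rng.binomial(1, 0.05, n) * 5.0,
    # lowly expressed, quiet gene: fails both criteria
    "QUIET1": np.abs(rng.normal(0.5, 0.3, n)),
}, index=[f"s{i}" for i in range(n)])

kept = rs.filter_genes(mat, cv_min=5.0, mean_min=3.0)
means = mat.mean()
cvs = mat.std(ddof=0) / mat.mean()
for g in mat.columns:
    status = "kept" if g in kept.columns else "dropped"
    print(f"{g:8s} mean={means[g]:6.2f}  CV={cvs[g]:6.2f}  -> {status}")
print(f"\n{kept.shape[1]} of {mat.shape[1]} genes pass (CV >= 5 or mean >= 3)")
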