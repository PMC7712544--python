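"""Single-variant additive association scan (Cochran-Armitage trend test).

Reference comparison for the forest pipeline; output is compatible with
standard Manhattan plotters (CHR, BP, SNP, P).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: conventional genome-wide significance line for plotting
GENOME_WIDE_ALPHA = 5e-8

_SCORES = np.array([0.0, 1.0, 2.0])


@dataclass
class GwasResult:
    table: pd.DataFrame  # columns CHR, BP, SNP, STAT, P, MONOMORPHIC

    def __len__(self):
        return len(self.table)

    def write_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)


def trend_test_counts(case_counts, ctrl_counts):
    """Cochran-Armitage trend chi-square for one 2x3 table with scores 0,1,2.

    Returns (statistic, p).  Degenerate tables (monomorphic variant or a
    missing class) give statistic 0, p 1.
    """
    r = np.asarray(case_counts, dtype=np.float64)
    s = np.asarray(ctrl_counts, dtype=np.float64)
    n_k = r + s
    N = n_k.sum()
    R = r.sum()
    if R == 0 or R == N:
        return 0.0, 1.0
    sx = float((_SCORES * n_k).sum())
    sxx = float((_SCORES ** 2 * n_k).sum())
    u = float((_SCORES * r).sum()) - R * sx / N
    var = R * (N - R) / N * (sxx - sx * sx / N) / N
    if var <= 0:
        return 0.0, 1.0
    stat = u * u / var
    return float(stat), float(stats.chi2.sf(stat, df=1))


def additive_scan(gm, pheno) -> GwasResult:
    """Trend test per variant, vectorized over the whole matrix."""
    X = gm.dosages
    y = np.asarray(pheno.status, dtype=np.float64)
    if y.min() == y.max():
        raise ValueError("both classes required")
    n, p = X.shape
    R = y.sum()

    n_k = np.empty((3, p))
    r_k = np.empty((3, p))
    for k in range(3):
        M = (X == k)
        n_k[k] = M.sum(axis=0)
        r_k[k] = y @ M

    N = float(n)
    sx = (_SCORES[:, None] * n_k).sum(axis=0)
    sxx = (_SCORES[:, None] ** 2 * n_k).sum(axis=0)
    u = (_SCORES[:, None] * r_k).sum(axis=0) - R * sx / N
    var = R * (N - R) / N * (sxx - sx * sx / N) / N

    mono = var <= 0
    stat = np.zeros(p)
    np.divide(u * u, var, out=stat, where=~mono)
    pvals = np.where(mono, 1.0, stats.chi2.sf(stat, df=1))

    table = pd.DataFrame({
        "CHR": [v.chrom for v in gm.variants],
        "BP": [v.pos for v in gm.variants],
        "SNP": [v.id for v in gm.variants],
        "STAT": stat,
        "P": pvals,
        "MONOMORPHIC": mono,
    })
    return GwasResult(table=table)
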