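"""Logistic-regression confirmation of screened pairs.

For each genotype-level combination (a, b) of a pair, indicators
I_a = [g_i == a] and I_b = [g_j == b] enter the model

    logit P(case) = b0 + b1*I_a + b2*I_b + b3*I_a*I_b

and the likelihood-ratio test of b3 = 0 gives the combination p-value.  The
model is saturated on the four (I_a, I_b) cells, so the full-model likelihood
has a closed form from the cell counts and only the reduced (additive) model
needs an iterative fit.  The minimum p over non-skipped combinations is kept
per pair (deliberately uncorrected for the within-pair search, and therefore
anti-conservative — the screening FDR happens across pairs).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .epistasis import bh_adjust

logger = logging.getLogger(__name__)


def _binomial_loglik(k, n):
    """Saturated log-likelihood contribution of cells with k cases of n."""
    k = np.asarray(k, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(k / n), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log((n - k) / n), 0.0)
    return float((t1 + t2).sum())


def _additive_loglik(k, n, ridge: float = 0.0):
    """Log-likelihood of the 3-parameter additive-logit model on the four
    aggregated (I_a, I_b) cells.  ``ridge`` adds an L2 penalty to the IRLS
    fallback path (penalty excluded from the returned likelihood)."""
    exog = np.array([[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]], dtype=float)
    endog = np.column_stack([k, n - k]).astype(float)
    if ridge == 0.0:
        model = sm.GLM(endog, exog, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
        # cell-count likelihood without the binomial coefficient, to match
        # the saturated formula used for the LRT
        mu = np.clip(res.mu, 1e-12, 1 - 1e-12)
        ll = float((k * np.log(mu) + (n - k) * np.log(1 - mu)).sum())
        if not np.isfinite(ll):
            raise RuntimeError("GLM log-likelihood not finite")
        return ll
    # ridge IRLS on the same 4-cell problem
    beta = np.zeros(3)
    for _ in range(200):
        eta = exog @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = n * mu * (1 - mu) + 1e-12
        z = eta + (k - n * mu) / W
        A = exog.T @ (W[:, None] * exog) + ridge * np.eye(3)
        beta_new = np.linalg.solve(A, exog.T @ (W * z))
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    eta = exog @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    return float((k * np.log(mu) + (n - k) * np.log(1 - mu)).sum())


@dataclass
class InteractionResult:
    feature_i: object
    feature_j: object
    min_p: float
    best_combination: tuple | None
    combinations: pd.DataFrame  # a, b, p, skipped + cell counts
    q_interaction: float = np.nan


def min_interaction_p(gi, gj, status, min_cell: int = 10,
                      feature_i="i", feature_j="j") -> InteractionResult:
    """Minimum LRT interaction p over all genotype-level combinations.

    Combinations where any of the four indicator cells holds fewer than
    ``min_cell`` subjects are skipped; if everything is skipped the pair
    gets p = 1.
    """
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    y = np.asarray(status, dtype=np.int64)
    levels_i = np.unique(gi)
    levels_j = np.unique(gj)

    rows = []
    for a, b in itertools.product(levels_i, levels_j):
        Ia = (gi == a).astype(np.int64)
        Ib = (gj == b).astype(np.int64)
        cell = 2 * Ia + Ib  # 0: (0,0), 1: (0,1), 2: (1,0), 3: (1,1)
        n = np.bincount(cell, minlength=4).astype(np.float64)
        k = np.bincount(cell, weights=y, minlength=4)
        row = {"a": a, "b": b,
               "n_00": n[0], "n_01": n[1], "n_10": n[2], "n_11": n[3],
               "k_00": k[0], "k_01": k[1], "k_10": k[2], "k_11": k[3]}
        if n.min() < min_cell:
            row.update(p=np.nan, skipped=True)
            rows.append(row)
            continue
        ll_full = _binomial_loglik(k, n)
        try:
            ll_red = _additive_loglik(k, n)
        except Exception:
            try:
                ll_red = _additive_loglik(k, n, ridge=1e-4)
                logger.warning("interaction GLM fell back to ridge for "
                               "(%s=%s, %s=%s)", feature_i, a, feature_j, b)
            except Exception:
                row.update(p=np.nan, skipped=True)
                rows.append(row)
                continue
        lrt = max(2.0 * (ll_full - ll_red), 0.0)
        row.update(p=float(stats.chi2.sf(lrt, df=1)), skipped=False)
        rows.append(row)

    comb = pd.DataFrame(rows)
    usable = comb[~comb["skipped"]]
    if len(usable) == 0:
        return InteractionResult(feature_i, feature_j, 1.0, None, comb)
    idx = usable["p"].idxmin()
    return InteractionResult(
        feature_i, feature_j, float(usable["p"].min()),
        (usable.loc[idx, "a"], usable.loc[idx, "b"]), comb)


def fdr_pass(results: list[InteractionResult],
             threshold: float = 0.05) -> pd.DataFrame:
    """BH step-up across pairs' minimum p-values; returns the per-pair table
    with q-values and a significance flag (all pairs are reported; the flag
    marks q < threshold)."""
    if not results:
        return pd.DataFrame(columns=["feature_i", "feature_j", "min_p",
                                     "best_a", "best_b", "q_interaction",
                                     "significant"])
    q = bh_adjust([r.min_p for r in results])
    rows = []
    for r, qv in zip(results, q):
        r.q_interaction = float(qv)
        a, b = r.best_combination if r.best_combination is not None else ("", "")
        rows.append({"feature_i": r.feature_i, "feature_j": r.feature_j,
                     "min_p": r.min_p, "best_a": a, "best_b": b,
                     "q_interaction": float(qv),
                     "significant": bool(qv < threshold)})
    return pd.DataFrame(rows)
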