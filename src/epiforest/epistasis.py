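"""Forest-structure epistasis screening.

Two statistics are read off the saved forest for every unordered pair of
selected features:

* paired selection frequency — do the two features land in the same tree
  more often than the independence expectation N * p_i * p_j predicts?
  (one-sided binomial, alternative "greater");
* selection asymmetry — when one feature splits a node, does the other
  preferentially appear under one daughter subtree?  The two-sided exact
  binomial null proportion is *opportunity-calibrated*: under independence a
  feature lands in a daughter subtree roughly in proportion to how many
  internal nodes that subtree has, so the null is the pooled opportunity
  share of the left daughters rather than 0.5 (a fixed 0.5 null is wildly
  anti-conservative whenever splits are unbalanced).

The two p-values are Fisher-combined (chi-square, 4 df) and Benjamini-
Hochberg adjusted across all pairs.  Pairs that co-occur less than expected
*and* show no asymmetry signal behave like linkage disequilibrium (a
redundant copy of a variant is never informative downstream of its partner)
and are labelled LD-like; they enter the multiplicity count but are never
retained.  Pairs with a co-occurrence deficit but strong asymmetry are kept
as epistasis candidates: interacting variants with marginal effects
systematically substitute for each other across trees, which depresses
co-occurrence below the independence expectation even though the
interaction is real.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .forest import ForestModel

DIRECTION_EPISTASIS = "epistasis-candidate"
DIRECTION_LD = "LD-like"


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=np.float64)
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Co-occurrence
# ---------------------------------------------------------------------------

def pair_cooccurrence(forest: ForestModel, features):
    """Per-tree co-occurrence counts for the selected features.

    Returns (t, p, N): t is the symmetric (k x k) matrix of trees containing
    both features, p the per-feature tree selection frequency, N the tree
    count.  A feature counts once per tree no matter how many nodes use it.
    """
    features = np.asarray(features)
    B = forest.feature_tree_matrix(features)
    t = B.T.astype(np.int64) @ B.astype(np.int64)
    p = B.mean(axis=0)
    return t, p, forest.n_trees


def paired_selection_test(t_ij: int, p_i: float, p_j: float, N: int) -> float:
    """P(X >= t_ij) for X ~ Binomial(N, p_i * p_j), exact tail."""
    e = p_i * p_j
    if e <= 0:
        return 1.0
    if t_ij <= 0:
        return 1.0
    return float(stats.binom.sf(t_ij - 1, N, e))


# ---------------------------------------------------------------------------
# Asymmetry
# ---------------------------------------------------------------------------

def _subtree_feature_matrix(tree, lookup: dict[int, int], k: int):
    """For each node, boolean vector over the k selected features present in
    the subtree rooted there (including the node's own split feature), plus
    the internal-node count of each subtree (the 'opportunity' for any
    feature to appear there)."""
    n_nodes = tree.n_nodes
    sub = np.zeros((n_nodes, k), dtype=bool)
    opp = np.zeros(n_nodes, dtype=np.int64)
    # children have larger indices than parents (preorder growth), so a
    # reverse sweep is a valid post-order accumulation
    for node in range(n_nodes - 1, -1, -1):
        f = tree.feature[node]
        if f < 0:
            continue
        sel = lookup.get(int(f))
        if sel is not None:
            sub[node, sel] = True
        sub[node] |= sub[tree.left[node]]
        sub[node] |= sub[tree.right[node]]
        opp[node] = 1 + opp[tree.left[node]] + opp[tree.right[node]]
    return sub, opp


def directional_asymmetry_counts(forest: ForestModel, features):
    """Asymmetry bookkeeping over ordered pairs.

    Returns (n_L, n_R, mu, var), all symmetric (k x k).  n_L[a, b] counts
    trees contributing a left-daughter observation for the unordered pair
    {a, b}: per tree exactly one splitter orientation is evaluated — the
    feature whose topmost split sits higher in the tree — and the partner's
    presence in that split's left/right daughter subtree increments n_L/n_R
    (both may increment when the partner appears on both sides).  One
    observation per tree keeps the draws independent; counting every split
    (or both orientations) counts a single placement of the partner several
    times and overdisperses the null.

    Every observation also contributes its tree-specific null probability of
    landing left, p_t = (internal nodes of left daughter) / (internal nodes
    of both daughters) — the structural opportunity share of that split.
    mu and var accumulate Sum p_t and Sum p_t(1 - p_t), the Poisson-binomial
    moments of n_L under the no-preference null.
    """
    features = np.asarray(features)
    k = len(features)
    lookup = {int(f): s for s, f in enumerate(features)}
    n_L = np.zeros((k, k), dtype=np.int64)
    n_R = np.zeros((k, k), dtype=np.int64)
    mu = np.zeros((k, k))
    var = np.zeros((k, k))
    for tree in forest.trees:
        if tree.n_nodes == 1:
            continue
        sub, opp = _subtree_feature_matrix(tree, lookup, k)
        top: dict[int, int] = {}
        for node in range(tree.n_nodes):  # preorder: ancestors come first
            f = tree.feature[node]
            if f < 0:
                continue
            i = lookup.get(int(f))
            if i is not None and i not in top:
                top[i] = node
        present = sorted(top, key=top.get)  # higher splits first
        for ai in range(len(present)):
            for bi in range(ai + 1, len(present)):
                a, b = present[ai], present[bi]
                for x, y in ((a, b), (b, a)):
                    node = top[x]
                    in_l = sub[tree.left[node], y]
                    in_r = sub[tree.right[node], y]
                    if not (in_l or in_r):
                        continue
                    o_l = opp[tree.left[node]]
                    o_r = opp[tree.right[node]]
                    p_t = o_l / (o_l + o_r) if (o_l + o_r) > 0 else 0.5
                    n_obs = int(in_l) + int(in_r)
                    for arr, val in ((n_L, int(in_l)), (n_R, int(in_r))):
                        arr[a, b] += val
                        arr[b, a] += val
                    mu[a, b] += n_obs * p_t
                    mu[b, a] = mu[a, b]
                    var[a, b] += n_obs * p_t * (1.0 - p_t)
                    var[b, a] = var[a, b]
                    break
    return n_L, n_R, mu, var


def asymmetry_test(n_L: int, n_R: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial test of n_L successes in n_L + n_R against
    null proportion ``p0``; no observations -> p = 1 by convention."""
    n = n_L + n_R
    if n == 0 or not (0.0 < p0 < 1.0):
        return 1.0
    return float(stats.binomtest(n_L, n, p0, alternative="two-sided").pvalue)


def _pooled_asymmetry(n_L, n_R, mu, var, a: int, b: int):
    """Test one unordered pair's observation counts against the
    Poisson-binomial opportunity null (normal approximation with continuity
    correction).  No observations, or zero null variance (every observation
    had only one possible side), give p = 1."""
    tot_L = int(n_L[a, b])
    tot_R = int(n_R[a, b])
    v = float(var[a, b])
    if tot_L + tot_R == 0 or v <= 0:
        return tot_L, tot_R, 1.0
    z = (abs(tot_L - float(mu[a, b])) - 0.5) / np.sqrt(v)
    p = 2.0 * float(stats.norm.sf(max(z, 0.0)))
    return tot_L, tot_R, min(p, 1.0)


def selection_asymmetry_test(forest: ForestModel, i: int, j: int):
    """Pooled-orientation asymmetry for one unordered pair of raw feature
    indices; returns (n_L, n_R, p)."""
    n_L, n_R, opp_L, opp_R = directional_asymmetry_counts(forest, [i, j])
    return _pooled_asymmetry(n_L, n_R, opp_L, opp_R, 0, 1)


# ---------------------------------------------------------------------------
# Combination and screening
# ---------------------------------------------------------------------------

def fisher_combine(p1: float, p2: float) -> float:
    """Fisher's method for two p-values: X = -2(ln p1 + ln p2) against
    chi-square with 4 df, whose survival is exp(-X/2) * (1 + X/2)."""
    ps = []
    for p in (p1, p2):
        if p <= 0:
            warnings.warn("p-value <= 0 clamped to 1e-300", stacklevel=2)
            p = 1e-300
        ps.append(min(p, 1.0))
    x = -2.0 * (np.log(ps[0]) + np.log(ps[1]))
    return float(stats.chi2.sf(x, df=4))


@dataclass
class PairScreenResult:
    table: pd.DataFrame
    n_trees: int

    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]

    def write_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)


def screen_pairs(forest: ForestModel, features, fdr_threshold: float = 0.05,
                 feature_ids=None, asym_alpha: float = 0.05) -> PairScreenResult:
    """Evaluate every unordered pair of ``features`` against the forest.

    BH adjustment runs across all evaluated pairs (LD-like included in the
    multiplicity count).  A pair is labelled LD-like — and never retained —
    when it co-occurs below the independence expectation *and* shows no
    selection asymmetry (p_asym >= asym_alpha): that is the signature of a
    redundant correlated variant rather than an interaction.  Retention
    requires q_ensemble < fdr_threshold and the epistasis-candidate label.
    """
    features = np.asarray(features)
    k = len(features)
    cols = ["feature_i", "feature_j", "t_ij", "n_trees", "p_i", "p_j",
            "expected", "p_cooccur", "n_L", "n_R", "p_asym", "p_fisher",
            "q_ensemble", "direction", "retained"]
    if k < 2:
        return PairScreenResult(table=pd.DataFrame(columns=cols),
                                n_trees=forest.n_trees)

    t, p, N = pair_cooccurrence(forest, features)
    n_L, n_R, opp_L, opp_R = directional_asymmetry_counts(forest, features)

    def name(s):
        return feature_ids[s] if feature_ids is not None else int(features[s])

    rows = []
    for a, b in itertools.combinations(range(k), 2):
        t_ab = int(t[a, b])
        e = float(p[a] * p[b])
        p_co = paired_selection_test(t_ab, p[a], p[b], N)
        L, R, p_as = _pooled_asymmetry(n_L, n_R, opp_L, opp_R, a, b)
        ld_like = (t_ab < N * e) and (p_as >= asym_alpha)
        rows.append({
            "feature_i": name(a), "feature_j": name(b), "t_ij": t_ab,
            "n_trees": N, "p_i": p[a], "p_j": p[b], "expected": N * e,
            "p_cooccur": p_co, "n_L": L, "n_R": R, "p_asym": p_as,
            "p_fisher": fisher_combine(p_co, p_as),
            "direction": DIRECTION_LD if ld_like else DIRECTION_EPISTASIS,
        })
    table = pd.DataFrame(rows)
    table["q_ensemble"] = bh_adjust(table["p_fisher"].to_numpy())
    table["retained"] = ((table["q_ensemble"] < fdr_threshold)
                         & (table["direction"] == DIRECTION_EPISTASIS))
    return PairScreenResult(table=table[cols], n_trees=N)
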