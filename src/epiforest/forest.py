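"""Class-weighted random forest on genotype dosages with full tree structure.

scikit-learn's forests do not expose per-tree candidate bookkeeping, weighted
bootstrap class balancing, or the shadow-permutation impurity correction this
pipeline needs, so the forest is implemented here directly on the 3-level
dosage encoding.  Dosage features are ordered numeric with only two possible
split points (0.5 and 1.5), which keeps exhaustive split search cheap and
vectorizable.

Key exports
-----------
train_forest            grow a ForestModel with optional shadow bookkeeping
corrected_impurity      debiased impurity importance + empirical p-values
permutation_importance  OOB permutation importance (class-weighted accuracy)
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class Tree:
    """Flat-array binary tree.  Internal nodes: ``feature >= 0`` with rule
    "dosage <= threshold goes left".  Leaves: ``feature == -1``."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    n_node: np.ndarray       # in-bag draw count reaching the node
    case_count: np.ndarray   # in-bag case draws
    ctrl_count: np.ndarray
    oob_idx: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int32))

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def features_used(self) -> np.ndarray:
        f = self.feature[self.feature >= 0]
        return np.unique(f)

    def leaf_mask(self) -> np.ndarray:
        return self.feature < 0

    def predict_leaf(self, X: np.ndarray, override_feature: int | None = None,
                     override_values: np.ndarray | None = None) -> np.ndarray:
        """Route rows of X to leaf indices.  ``override_feature`` substitutes
        a column (used for OOB permutation) without copying X."""
        pos = np.zeros(X.shape[0], dtype=np.int32)
        while True:
            feat = self.feature[pos]
            active = feat >= 0
            if not active.any():
                return pos
            ai = np.flatnonzero(active)
            f = feat[ai]
            vals = X[ai, f].astype(np.float32)
            if override_feature is not None:
                ov = f == override_feature
                if ov.any():
                    vals[ov] = override_values[ai[ov]]
            go_left = vals <= self.threshold[pos[ai]]
            pos[ai] = np.where(go_left, self.left[pos[ai]], self.right[pos[ai]])

    def predict_class(self, X: np.ndarray, **kw) -> np.ndarray:
        leaves = self.predict_leaf(X, **kw)
        return (self.case_count[leaves] > self.ctrl_count[leaves]).astype(np.int8)

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "n_node": self.n_node.tolist(),
            "case_count": self.case_count.tolist(),
            "ctrl_count": self.ctrl_count.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Tree":
        return cls(
            feature=np.asarray(d["feature"], dtype=np.int32),
            threshold=np.asarray(d["threshold"], dtype=np.float32),
            left=np.asarray(d["left"], dtype=np.int32),
            right=np.asarray(d["right"], dtype=np.int32),
            n_node=np.asarray(d["n_node"], dtype=np.float64),
            case_count=np.asarray(d["case_count"], dtype=np.float64),
            ctrl_count=np.asarray(d["ctrl_count"], dtype=np.float64),
        )


@dataclass
class ForestModel:
    trees: list[Tree]
    n_features: int
    n_subjects: int
    mtry_fraction: float
    min_node_fraction: float
    class_sampling_weights: tuple[float, float]  # (control, case) draw prob per subject
    seed: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def feature_tree_matrix(self, features: np.ndarray | None = None) -> np.ndarray:
        """Boolean (n_trees x len(features)) presence matrix; a feature counts
        once per tree regardless of how many nodes use it."""
        if features is None:
            features = np.arange(self.n_features)
        features = np.asarray(features)
        B = np.zeros((self.n_trees, len(features)), dtype=bool)
        lookup = {int(f): k for k, f in enumerate(features)}
        for t, tree in enumerate(self.trees):
            for f in tree.features_used():
                k = lookup.get(int(f))
                if k is not None:
                    B[t, k] = True
        return B

    def tree_selection_frequency(self) -> np.ndarray:
        """p_i = (# trees containing feature i) / n_trees."""
        counts = np.zeros(self.n_features, dtype=np.int64)
        for tree in self.trees:
            counts[tree.features_used()] += 1
        return counts / float(self.n_trees)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        votes = np.zeros(X.shape[0])
        for tree in self.trees:
            votes += tree.predict_class(X)
        return votes / self.n_trees

    # -- JSON tree schema -------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "schema": "epiforest-tree-v1",
            "n_trees": self.n_trees,
            "n_features": self.n_features,
            "n_subjects": self.n_subjects,
            "mtry_fraction": self.mtry_fraction,
            "min_node_fraction": self.min_node_fraction,
            "class_sampling_weights": list(self.class_sampling_weights),
            "seed": self.seed,
            "trees": [t.to_dict() for t in self.trees],
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ForestModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        if payload.get("schema") != "epiforest-tree-v1":
            raise ValueError("not an epiforest tree schema file")
        return cls(
            trees=[Tree.from_dict(d) for d in payload["trees"]],
            n_features=payload["n_features"],
            n_subjects=payload["n_subjects"],
            mtry_fraction=payload["mtry_fraction"],
            min_node_fraction=payload["min_node_fraction"],
            class_sampling_weights=tuple(payload["class_sampling_weights"]),
            seed=payload["seed"],
        )


@dataclass
class TrainingContext:
    """Forest plus the per-candidate bookkeeping accumulated while growing."""

    forest: ForestModel
    raw_gini: np.ndarray        # impurity decrease at nodes where chosen
    corrected: np.ndarray       # actual minus shadow decrease at candidacies
    candidate_counts: np.ndarray


@dataclass
class ImportanceTable:
    """Per-feature importance scores for one forest."""

    raw_impurity: np.ndarray
    corrected: np.ndarray | None = None
    p_value: np.ndarray | None = None
    permutation: np.ndarray | None = None
    selection_frequency: np.ndarray | None = None
    p_unstable: bool = False

    def to_frame(self, ids=None):
        import pandas as pd

        n = len(self.raw_impurity)
        data = {"feature": ids if ids is not None else np.arange(n),
                "raw_impurity": self.raw_impurity}
        for name in ("corrected", "p_value", "permutation", "selection_frequency"):
            v = getattr(self, name)
            if v is not None:
                data[name] = v
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _gini_gain(t0, t1, c10, c11, n_total, c1_total):
    """Vectorized two-threshold split score for 3-level ordered features.

    Parameters are per-candidate arrays of weighted level counts
    (t* totals, c1* cases).  Returns (gain, threshold) maximizing the
    decrease in weighted Gini; invalid splits get gain 0.
    """
    c0_total = n_total - c1_total
    parent = (c1_total * c1_total + c0_total * c0_total) / n_total

    best_gain = np.zeros_like(t0, dtype=np.float64)
    best_thr = np.full_like(t0, 0.5, dtype=np.float32)
    for thr, nL, c1L in ((0.5, t0, c10), (1.5, t0 + t1, c10 + c11)):
        nR = n_total - nL
        c1R = c1_total - c1L
        valid = (nL > 0) & (nR > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            c0L = nL - c1L
            c0R = nR - c1R
            score = (c1L * c1L + c0L * c0L) / nL + (c1R * c1R + c0R * c0R) / nR
        gain = np.where(valid, score - parent, 0.0)
        better = gain > best_gain
        best_gain = np.where(better, gain, best_gain)
        best_thr = np.where(better, np.float32(thr), best_thr)
    return best_gain, best_thr


def _grow_tree(X, y, prob, rng, mtry, min_node_size, shadow,
               raw_gini, corrected, candidate_counts):
    n, p = X.shape
    draw = rng.choice(n, size=n, replace=True, p=prob)
    counts = np.bincount(draw, minlength=n)
    inbag = np.flatnonzero(counts)
    oob = np.flatnonzero(counts == 0).astype(np.int32)

    feature, threshold, left, right = [], [], [], []
    n_node, case_count, ctrl_count = [], [], []

    def new_node():
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        n_node.append(0.0)
        case_count.append(0.0)
        ctrl_count.append(0.0)
        return len(feature) - 1

    root = new_node()
    stack = [(root, inbag, counts[inbag].astype(np.float64))]
    while stack:
        node, idx, w = stack.pop()
        yb = y[idx]
        n_draws = float(w.sum())
        c1 = float((w * yb).sum())
        n_node[node] = n_draws
        case_count[node] = c1
        ctrl_count[node] = n_draws - c1

        if n_draws <= min_node_size or c1 == 0.0 or c1 == n_draws:
            continue

        cand = rng.choice(p, size=mtry, replace=False)
        Xs = X[np.ix_(idx, cand)]
        M0 = (Xs == 0).astype(np.float32)
        M1 = (Xs == 1).astype(np.float32)
        wv = w.astype(np.float32)
        wy = (w * yb).astype(np.float32)
        t0 = wv @ M0
        t1 = wv @ M1
        c10 = wy @ M0
        c11 = wy @ M1
        gain, thr = _gini_gain(t0.astype(np.float64), t1.astype(np.float64),
                               c10.astype(np.float64), c11.astype(np.float64),
                               n_draws, c1)

        candidate_counts[cand] += 1
        if shadow:
            perm = rng.permutation(len(idx))
            t0s = wv[perm] @ M0
            t1s = wv[perm] @ M1
            c10s = wy[perm] @ M0
            c11s = wy[perm] @ M1
            gain_s, _ = _gini_gain(t0s.astype(np.float64), t1s.astype(np.float64),
                                   c10s.astype(np.float64), c11s.astype(np.float64),
                                   n_draws, c1)
            corrected[cand] += gain - gain_s  # cand indices are unique

        best = int(np.argmax(gain))
        if gain[best] <= _EPS:
            continue
        f = int(cand[best])
        t = float(thr[best])
        raw_gini[f] += gain[best]

        go_left = Xs[:, best] <= t
        li, lw = idx[go_left], w[go_left]
        ri, rw = idx[~go_left], w[~go_left]
        feature[node] = f
        threshold[node] = t
        lnode = new_node()
        rnode = new_node()
        left[node] = lnode
        right[node] = rnode
        stack.append((rnode, ri, rw))
        stack.append((lnode, li, lw))

    return Tree(
        feature=np.asarray(feature, dtype=np.int32),
        threshold=np.asarray(threshold, dtype=np.float32),
        left=np.asarray(left, dtype=np.int32),
        right=np.asarray(right, dtype=np.int32),
        n_node=np.asarray(n_node, dtype=np.float64),
        case_count=np.asarray(case_count, dtype=np.float64),
        ctrl_count=np.asarray(ctrl_count, dtype=np.float64),
        oob_idx=oob,
    )


def train_forest(X, y, n_trees: int = 1000, mtry_fraction: float = 1 / 3,
                 min_node_fraction: float = 0.1, seed: int = 0,
                 shadow: bool = False) -> TrainingContext:
    """Grow a class-weighted random forest.

    Each tree draws an n-sized bootstrap where every case has sampling
    probability proportional to 1/n_cases and every control 1/n_controls, so
    the expected class balance in-bag is 50:50 regardless of cohort
    imbalance.  At each node ``ceil(mtry_fraction * p)`` candidate features
    are sampled without replacement and the best Gini-decrease split over
    the dosage thresholds {0.5, 1.5} is taken.  Nodes whose in-bag draw
    count is at most ``min_node_fraction * n`` become leaves.

    With ``shadow=True`` every candidacy also evaluates the same feature on
    a within-node permutation of the sample weights/labels, accumulating the
    corrected impurity importance (actual minus shadow gain).

    Returns a TrainingContext; the ForestModel is ``ctx.forest``.
    """
    X = np.ascontiguousarray(X, dtype=np.int8)
    y = np.asarray(y, dtype=np.int8)
    n, p = X.shape
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if not (0 < mtry_fraction <= 1):
        raise ValueError("mtry_fraction must be in (0, 1]")
    n_cases = int(y.sum())
    n_ctrls = n - n_cases
    if n_cases == 0 or n_ctrls == 0:
        raise ValueError("phenotype must contain both classes")

    w_case = 1.0 / (2.0 * n_cases)
    w_ctrl = 1.0 / (2.0 * n_ctrls)
    prob = np.where(y == 1, w_case, w_ctrl)
    prob = prob / prob.sum()

    mtry = int(np.ceil(mtry_fraction * p))
    min_node_size = min_node_fraction * n

    raw_gini = np.zeros(p)
    corrected = np.zeros(p)
    candidate_counts = np.zeros(p, dtype=np.int64)

    ss = np.random.SeedSequence(seed)
    trees = []
    for child in ss.spawn(n_trees):
        rng = np.random.Generator(np.random.PCG64(child))
        trees.append(_grow_tree(X, y, prob, rng, mtry, min_node_size, shadow,
                                raw_gini, corrected, candidate_counts))

    forest = ForestModel(
        trees=trees, n_features=p, n_subjects=n,
        mtry_fraction=mtry_fraction, min_node_fraction=min_node_fraction,
        class_sampling_weights=(w_ctrl, w_case), seed=seed,
    )
    # normalize importances by cohort size so scales are n-free
    return TrainingContext(forest=forest, raw_gini=raw_gini / n,
                           corrected=corrected / n,
                           candidate_counts=candidate_counts)


# ---------------------------------------------------------------------------
# Importance measures
# ---------------------------------------------------------------------------

def corrected_impurity(ctx: TrainingContext) -> ImportanceTable:
    """Corrected impurity importance with mirrored-null empirical p-values.

    The null pool is the mirror image of all non-positive corrected scores;
    p(feature) = (1 + #null >= score) / (1 + #null).  Features that were
    never candidates anywhere keep score 0.
    """
    scores = ctx.corrected
    nonpos = scores[scores <= 0]
    null = -nonpos
    unstable = len(null) < 100
    if unstable:
        warnings.warn(
            f"only {len(null)} non-positive corrected scores; "
            "empirical p-values are unstable", stacklevel=2)
    if len(null) == 0:
        pvals = np.ones_like(scores)
    else:
        sorted_null = np.sort(null)
        # count of null >= score via searchsorted on the sorted pool
        ge = len(sorted_null) - np.searchsorted(sorted_null, scores, side="left")
        pvals = (1.0 + ge) / (1.0 + len(sorted_null))
    return ImportanceTable(
        raw_impurity=ctx.raw_gini.copy(),
        corrected=scores.copy(),
        p_value=pvals,
        selection_frequency=ctx.forest.tree_selection_frequency(),
        p_unstable=unstable,
    )


def _weighted_accuracy(pred, truth, class_w):
    w = class_w[truth]
    return float((w * (pred == truth)).sum() / w.sum())


def permutation_importance(forest: ForestModel, X, y,
                           seed: int = 0) -> ImportanceTable:
    """OOB permutation importance using class-weighted accuracy.

    For each tree: baseline OOB accuracy minus accuracy after permuting one
    feature's OOB values; features absent from a tree contribute 0 for that
    tree; trees without OOB samples are skipped.  The mean is over the
    trees that had OOB samples.
    """
    X = np.ascontiguousarray(X, dtype=np.int8)
    y = np.asarray(y, dtype=np.int8)
    p = forest.n_features
    n_cases = max(int(y.sum()), 1)
    n_ctrls = max(len(y) - int(y.sum()), 1)
    class_w = np.array([1.0 / n_ctrls, 1.0 / n_cases])

    imp = np.zeros(p)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    n_used = 0
    for tree in forest.trees:
        oob = tree.oob_idx
        if len(oob) == 0:
            continue
        n_used += 1
        Xo = X[oob]
        yo = y[oob]
        base = _weighted_accuracy(tree.predict_class(Xo), yo, class_w)
        for f in tree.features_used():
            perm_vals = Xo[rng.permutation(len(oob)), f].astype(np.float32)
            pred = tree.predict_class(Xo, override_feature=int(f),
                                      override_values=perm_vals)
            imp[f] += base - _weighted_accuracy(pred, yo, class_w)
    if n_used == 0:
        raise ValueError("no tree had OOB samples")
    imp /= n_used
    return ImportanceTable(raw_impurity=np.zeros(p), permutation=imp,
                           selection_frequency=forest.tree_selection_frequency())
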