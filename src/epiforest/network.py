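"""Condense interacting pairs into variant networks and fit per-network
decision trees whose terminal nodes report normalized odds ratios.

Networks are the connected components of the pair graph (A|B and A|C merge
into A|B|C).  Each network gets a conditional-inference-style decision tree:
at every node the candidate features are tested for independence against the
outcome (chi-square on the genotype table), the minimum Bonferroni-adjusted
p decides whether to split, and the split partition is the binary genotype
grouping with the smallest chi-square p.  This mirrors the architecture of
ctree (association-test-driven splits with multiplicity-adjusted stopping)
without its permutation-test machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class VariantNetwork:
    network_id: int
    members: list            # sorted feature labels
    pairs: list[tuple]       # (i, j, q_value)

    def __contains__(self, item):
        return item in self.members


def condense_networks(pairs) -> list[VariantNetwork]:
    """Connected components of the pair graph, ordered by smallest member.

    ``pairs`` is an iterable of (i, j) or (i, j, q).
    """
    g = nx.Graph()
    qmap = {}
    for pair in pairs:
        i, j = pair[0], pair[1]
        q = pair[2] if len(pair) > 2 else np.nan
        g.add_edge(i, j)
        qmap[frozenset((i, j))] = q
    networks = []
    comps = sorted((sorted(c, key=str) for c in nx.connected_components(g)),
                   key=lambda c: str(c[0]))
    for nid, comp in enumerate(comps, start=1):
        members = set(comp)
        members_pairs = [(i, j, qmap[frozenset((i, j))])
                         for i, j in g.edges(comp) if i in members and j in members]
        networks.append(VariantNetwork(network_id=nid, members=sorted(comp, key=str),
                                       pairs=sorted(members_pairs, key=str)))
    return networks


# ---------------------------------------------------------------------------
# Network decision trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    node_id: int
    n_cases: int
    n_controls: int
    feature: object = None           # None for terminal nodes
    left_levels: tuple = ()          # genotype levels routed left
    p_select: float = np.nan         # Bonferroni-adjusted selection p
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    # terminal annotations (filled by terminal_odds_ratios)
    odds_ratio: float = np.nan
    or_p_value: float = np.nan
    or_corrected: bool = False

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def leaves(self):
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())


@dataclass
class NetworkTree:
    network: VariantNetwork
    root: TreeNode
    alpha: float
    min_leaf: int
    normalization: str = ""
    feature_columns: dict = field(default_factory=dict)

    def leaves(self):
        return self.root.leaves()

    def to_outline(self) -> str:
        lines = []

        def walk(node, indent, label):
            pad = "  " * indent
            if node.is_leaf:
                extra = ""
                if np.isfinite(node.odds_ratio):
                    extra = f" OR={node.odds_ratio:.3f} p={node.or_p_value:.3g}"
                lines.append(f"{pad}{label}leaf#{node.node_id} "
                             f"[{node.n_cases}/{node.n_controls}]{extra}")
                return
            lines.append(
                f"{pad}{label}node#{node.node_id} {node.feature} in "
                f"{set(node.left_levels)} (p_adj={node.p_select:.3g}) "
                f"[{node.n_cases}/{node.n_controls}]")
            walk(node.left, indent + 1, "L: ")
            walk(node.right, indent + 1, "R: ")

        walk(self.root, 0, "")
        return "\n".join(lines)

    def to_dot(self) -> str:
        lines = ["digraph network_tree {"]

        def walk(node):
            if node.is_leaf:
                label = f"{node.n_cases}/{node.n_controls}"
                if np.isfinite(node.odds_ratio):
                    label += f"\\nOR={node.odds_ratio:.2f}"
                lines.append(f'  n{node.node_id} [shape=box label="{label}"];')
                return
            lines.append(f'  n{node.node_id} [label="{node.feature}"];')
            lines.append(f'  n{node.node_id} -> n{node.left.node_id} '
                         f'[label="{set(node.left_levels)}"];')
            lines.append(f'  n{node.node_id} -> n{node.right.node_id};')
            walk(node.left)
            walk(node.right)

        walk(self.root)
        lines.append("}")
        return "\n".join(lines)

    def leaf_table(self) -> pd.DataFrame:
        rows = [{"leaf": lf.node_id, "n_cases": lf.n_cases,
                 "n_controls": lf.n_controls, "odds_ratio": lf.odds_ratio,
                 "p_value": lf.or_p_value, "zero_cell_corrected": lf.or_corrected}
                for lf in self.leaves()]
        return pd.DataFrame(rows)


def _binary_groupings(levels):
    """Binary partitions of the observed genotype levels.  For the ordered
    3-level dosage these are {0}|{1,2}, {0,1}|{2} and {0,2}|{1}."""
    levels = sorted(levels)
    if len(levels) == 2:
        return [((levels[0],), (levels[1],))]
    if len(levels) == 3:
        a, b, c = levels
        return [((a,), (b, c)), ((a, b), (c,)), ((a, c), (b,))]
    return []


def _chi2_p(table):
    table = np.asarray(table, dtype=np.float64)
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return 1.0
    try:
        return float(stats.chi2_contingency(table, correction=False)[1])
    except ValueError:
        return 1.0


def fit_network_tree(network: VariantNetwork, columns: dict, status,
                     alpha: float = 0.05, min_leaf: int = 20) -> NetworkTree:
    """Fit the association-test-driven decision tree for one network.

    ``columns`` maps member label -> genotype/covariate vector.  Splitting
    stops when no candidate's Bonferroni-adjusted chi-square p is below
    ``alpha`` or when every admissible partition would create a child
    smaller than ``min_leaf``.
    """
    y = np.asarray(status, dtype=np.int64)
    feats = [m for m in network.members if m in columns]
    counter = {"next_id": 0}

    def build(idx):
        nid = counter["next_id"]
        counter["next_id"] += 1
        yb = y[idx]
        node = TreeNode(node_id=nid, n_cases=int(yb.sum()),
                        n_controls=int(len(yb) - yb.sum()))
        if node.n_cases == 0 or node.n_controls == 0:
            return node

        # candidate selection: chi-square on the full genotype table
        cand = []
        for m in feats:
            g = np.asarray(columns[m])[idx]
            levels = np.unique(g)
            if len(levels) < 2:
                continue
            table = np.stack([
                np.array([(yb[g == lv] == 1).sum() for lv in levels]),
                np.array([(yb[g == lv] == 0).sum() for lv in levels]),
            ])
            cand.append((m, levels, _chi2_p(table)))
        if not cand:
            return node
        n_tested = len(cand)
        cand.sort(key=lambda t: t[2])
        m, levels, p_raw = cand[0]
        p_adj = min(1.0, p_raw * n_tested)
        if p_adj >= alpha:
            return node

        # partition: binary grouping minimizing the 2x2 chi-square p,
        # subject to the min_leaf constraint
        g = np.asarray(columns[m])[idx]
        options = []
        for left_levels, right_levels in _binary_groupings(levels):
            mask = np.isin(g, left_levels)
            nl, nr = int(mask.sum()), int((~mask).sum())
            if nl < min_leaf or nr < min_leaf:
                continue
            table = [[(yb[mask] == 1).sum(), (yb[~mask] == 1).sum()],
                     [(yb[mask] == 0).sum(), (yb[~mask] == 0).sum()]]
            options.append((_chi2_p(table), left_levels, mask))
        if not options:
            return node
        options.sort(key=lambda t: t[0])
        _, left_levels, mask = options[0]

        node.feature = m
        node.left_levels = tuple(left_levels)
        node.p_select = p_adj
        node.left = build(idx[mask])
        node.right = build(idx[~mask])
        return node

    root = build(np.arange(len(y)))
    return NetworkTree(network=network, root=root, alpha=alpha,
                       min_leaf=min_leaf, feature_columns=dict(columns))


def terminal_odds_ratios(tree: NetworkTree, status,
                         mode: str = "complement") -> NetworkTree:
    """Annotate terminal nodes with normalized odds ratios.

    overall mode:    OR = (cases_leaf/controls_leaf) / (cases_total/controls_total)
    complement mode: denominator odds use the subjects *outside* the leaf.
    The p-value is Fisher's exact test on the leaf-vs-rest 2x2 table; zero
    cells in the OR get the Haldane-Anscombe 0.5 correction with a flag.
    """
    if mode not in ("overall", "complement"):
        raise ValueError("mode must be 'overall' or 'complement'")
    y = np.asarray(status, dtype=np.int64)
    total_cases = int(y.sum())
    total_ctrls = int(len(y) - y.sum())

    for leaf in tree.leaves():
        a, b = leaf.n_cases, leaf.n_controls
        if a + b == 0:
            raise ValueError("empty leaf")
        if mode == "overall":
            c, d = total_cases, total_ctrls
        else:
            c, d = total_cases - a, total_ctrls - b
        corrected = False
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
        if min(aa, bb, cc, dd) == 0:
            aa, bb, cc, dd = aa + 0.5, bb + 0.5, cc + 0.5, dd + 0.5
            corrected = True
        leaf.odds_ratio = (aa / bb) / (cc / dd)
        leaf.or_corrected = corrected
        _, leaf.or_p_value = stats.fisher_exact(
            [[a, b], [total_cases - a, total_ctrls - b]])
    tree.normalization = mode
    return tree
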