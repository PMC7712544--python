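"""Consensus feature selection across replicate forests (relative permutation
importance thresholded in every forest)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest import ForestModel, permutation_importance, train_forest

logger = logging.getLogger(__name__)


@dataclass
class R2vimResult:
    vim: np.ndarray            # (n_forests, p) permutation importance
    relative: np.ndarray       # (n_forests, p) VIM / |most negative VIM in forest|
    min_relative: np.ndarray   # (p,) min over forests
    selected: np.ndarray       # (p,) bool, min_relative >= threshold
    threshold: float
    final_forest: ForestModel  # last forest, kept intact for epistasis screening
    fallback_forests: list[int]  # forests whose min VIM was non-negative

    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)

    def to_frame(self, ids=None) -> pd.DataFrame:
        p = self.vim.shape[1]
        data = {"feature": ids if ids is not None else np.arange(p)}
        for f in range(self.vim.shape[0]):
            data[f"vim_{f + 1}"] = self.vim[f]
            data[f"rel_{f + 1}"] = self.relative[f]
        data["min_relative"] = self.min_relative
        data["selected"] = self.selected
        return pd.DataFrame(data)


def relative_importance(vim: np.ndarray) -> tuple[np.ndarray, bool]:
    """r_v = VIM_v / |min_v VIM| for one forest.

    The denominator is the magnitude of the most negative importance; if no
    importance is negative (rare, degenerate forests) it falls back to the
    smallest strictly positive magnitude.  Returns (relative, used_fallback).
    """
    vmin = vim.min()
    if vmin < 0:
        return vim / abs(vmin), False
    pos = np.abs(vim[vim != 0])
    denom = pos.min() if len(pos) else 1.0
    logger.warning("relative_importance: no negative VIM; falling back to "
                   "smallest positive magnitude %g", denom)
    return vim / denom, True


def run_r2vim(X, y, n_forests: int = 11, n_trees: int = 10_000,
              mtry_fraction: float = 1 / 3, min_node_fraction: float = 0.1,
              threshold: float = 1.0, seed: int = 0) -> R2vimResult:
    """Train ``n_forests`` forests on the screened feature set and select
    features whose relative permutation importance is at least ``threshold``
    in every forest.  Forests are independent with sequential seed streams;
    the last forest is returned intact for downstream epistasis screening.
    """
    X = np.ascontiguousarray(X, dtype=np.int8)
    p = X.shape[1]
    ss = np.random.SeedSequence([seed, 0x72])
    children = ss.spawn(n_forests)

    vims = np.empty((n_forests, p))
    rels = np.empty((n_forests, p))
    fallback = []
    final_forest = None
    for f in range(n_forests):
        fseed = int(children[f].generate_state(1)[0] % (2 ** 31))
        ctx = train_forest(X, y, n_trees=n_trees, mtry_fraction=mtry_fraction,
                           min_node_fraction=min_node_fraction, seed=fseed,
                           shadow=False)
        imp = permutation_importance(ctx.forest, X, y, seed=fseed + 1)
        vims[f] = imp.permutation
        rels[f], used_fb = relative_importance(vims[f])
        if used_fb:
            fallback.append(f)
        final_forest = ctx.forest

    min_rel = rels.min(axis=0)
    return R2vimResult(
        vim=vims, relative=rels, min_relative=min_rel,
        selected=min_rel >= threshold, threshold=threshold,
        final_forest=final_forest, fallback_forests=fallback,
    )
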