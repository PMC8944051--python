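"""Recursive partitioning with permutation-test split selection.

A light-weight conditional-inference-style tree for categorical
responses: at each node, every feature is screened with a
permutation-based independence test (the maximum, over a quantile grid
of candidate cutpoints, of the Pearson chi-square statistic of the
label-by-side contingency table; its null distribution is obtained by
permuting the labels).  P-values are Bonferroni-corrected across the
features screened at the node; the node splits on the most significant
feature at the statistic-maximising cutpoint, and growing stops when no
feature is significant at ``alpha`` or a split would leave a child with
less than ``min_node_frac`` of the full data set.  Leaves report label
proportions.

This deliberately trades the exact asymptotics of the reference
conditional-inference framework for a transparent Monte-Carlo test; the
contract is recovery of the dominant splits, not leaf-for-leaf agreement
with any particular library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TreeNode", "PartitionTree"]


@dataclass
class TreeNode:
    n: int
    proportions: dict
    depth: int
    feature: str | None = None
    cutpoint: float | None = None
    statistic: float | None = None
    p_value: float | None = None
    left: "TreeNode | None" = field(default=None, repr=False)
    right: "TreeNode | None" = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d = {"n": self.n, "proportions": self.proportions}
        if not self.is_leaf:
            d.update(feature=self.feature, cutpoint=self.cutpoint,
                     statistic=self.statistic, p_value=self.p_value,
                     left=self.left.to_dict(), right=self.right.to_dict())
        return d

    def render(self, indent: str = "") -> str:
        if self.is_leaf:
            props = ", ".join(f"{k}: {v:.3f}" for k, v in sorted(self.proportions.items()))
            return f"{indent}leaf n={self.n} [{props}]\n"
        out = (f"{indent}{self.feature} <= {self.cutpoint:.4g} "
               f"(p={self.p_value:.4g}, n={self.n})\n")
        out += self.left.render(indent + "  ")
        out += self.right.render(indent + "  ")
        return out


def _chi2_profile(bins: np.ndarray, y: np.ndarray, n_bins: int, n_labels: int) -> np.ndarray:
    """Chi-square statistic of the 2xL table for every cut between bins.

    ``bins`` assigns each observation to one of ``n_bins`` ordered bins;
    cutting after bin c sends bins <= c left.  Returns the statistic for
    c = 0 .. n_bins-2.
    """
    counts = np.bincount(bins * n_labels + y, minlength=n_bins * n_labels)
    counts = counts.reshape(n_bins, n_labels)
    left = np.cumsum(counts, axis=0)[:-1]          # (C, L)
    total = counts.sum(axis=0)                     # (L,)
    n = total.sum()
    right = total[None, :] - left
    nl = left.sum(axis=1, keepdims=True)
    nr = n - nl
    with np.errstate(invalid="ignore", divide="ignore"):
        el = nl * total[None, :] / n
        er = nr * total[None, :] / n
        stat = np.where(el > 0, (left - el) ** 2 / np.where(el > 0, el, 1), 0.0).sum(axis=1)
        stat += np.where(er > 0, (right - er) ** 2 / np.where(er > 0, er, 1), 0.0).sum(axis=1)
    stat[(nl[:, 0] == 0) | (nr[:, 0] == 0)] = 0.0
    return stat


@dataclass
class PartitionTree:
    """Permutation-test recursive partitioning of labels over features."""

    alpha: float = 0.05
    min_node_frac: float = 0.05
    n_permutations: int = 499
    max_candidates: int = 100
    max_depth: int | None = None
    random_state: int | None = 0

    root: TreeNode | None = field(default=None, init=False)
    feature_names_: list[str] = field(default_factory=list, init=False)
    classes_: np.ndarray | None = field(default=None, init=False)

    def fit(self, X: pd.DataFrame, y) -> "PartitionTree":
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if len(X) != y.shape[0]:
            raise ValueError("X and y lengths differ")
        self.feature_names_ = list(X.columns)
        self.classes_, y_codes = np.unique(y, return_inverse=True)
        rng = np.random.default_rng(self.random_state)
        Xv = X.to_numpy(dtype=float)
        self._n_total = len(X)
        self.root = self._grow(Xv, y_codes.astype(np.int64), rng, depth=0)
        return self

    # -- internals ---------------------------------------------------------

    def _proportions(self, y: np.ndarray) -> dict:
        counts = np.bincount(y, minlength=self.classes_.size)
        return {str(c): float(v) / y.size for c, v in zip(self.classes_, counts)}

    def _candidates(self, x: np.ndarray) -> np.ndarray:
        """Candidate cutpoints: interior quantile grid of the feature."""
        qs = np.linspace(0.0, 1.0, self.max_candidates + 2)[1:-1]
        cuts = np.unique(np.quantile(x, qs))
        return cuts[(cuts > x.min()) & (cuts < x.max())]

    def _grow(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator, depth: int) -> TreeNode:
        node = TreeNode(n=y.size, proportions=self._proportions(y), depth=depth)
        if (self.max_depth is not None and depth >= self.max_depth) or \
                np.unique(y).size < 2 or y.size < 2:
            return node

        min_child = max(1, int(np.ceil(self.min_node_frac * self._n_total)))
        if y.size < 2 * min_child:
            return node

        L = self.classes_.size
        screens = []
        for j, name in enumerate(self.feature_names_):
            x = X[:, j]
            cuts = self._candidates(x)
            if cuts.size == 0:
                continue  # constant feature at this node
            # side='left' puts observations equal to a cutpoint on its
            # left, matching the `x <= cut` split mask
            bins = np.searchsorted(cuts, x, side="left")
            n_bins = cuts.size + 1
            # sizes of the left side at every cut, for the child-size floor
            sizes = np.cumsum(np.bincount(bins, minlength=n_bins))[:-1]
            valid = (sizes >= min_child) & (y.size - sizes >= min_child)
            if not valid.any():
                continue
            profile = _chi2_profile(bins, y, n_bins, L)
            obs = profile[valid].max()
            best_cut = cuts[valid][profile[valid].argmax()]
            screens.append((j, name, bins, n_bins, valid, obs, best_cut))
        if not screens:
            return node

        B = self.n_permutations
        exceed = np.zeros(len(screens))
        for _ in range(B):
            yp = rng.permutation(y)
            for s, (j, name, bins, n_bins, valid, obs, _cut) in enumerate(screens):
                stat = _chi2_profile(bins, yp, n_bins, L)[valid].max()
                if stat >= obs:
                    exceed[s] += 1
        p = (1.0 + exceed) / (B + 1.0)
        p_adj = np.minimum(1.0, p * len(screens))

        order = np.lexsort((-np.array([s[5] for s in screens]), p_adj))
        best = order[0]
        if p_adj[best] >= self.alpha:
            return node

        j, name, bins, n_bins, valid, obs, cut = screens[best]
        mask = X[:, j] <= cut
        node.feature = name
        node.cutpoint = float(cut)
        node.statistic = float(obs)
        node.p_value = float(p_adj[best])
        node.left = self._grow(X[mask], y[mask], rng, depth + 1)
        node.right = self._grow(X[~mask], y[~mask], rng, depth + 1)
        return node

    # -- inspection --------------------------------------------------------

    def render(self) -> str:
        self._check_fitted()
        return self.root.render()

    def to_dict(self) -> dict:
        self._check_fitted()
        return self.root.to_dict()

    def depth(self) -> int:
        self._check_fitted()

        def _d(node: TreeNode) -> int:
            return 0 if node.is_leaf else 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    def n_leaves(self) -> int:
        self._check_fitted()

        def _c(node: TreeNode) -> int:
            return 1 if node.is_leaf else _c(node.left) + _c(node.right)

        return _c(self.root)

    def _check_fitted(self) -> None:
        if self.root is None:
            raise RuntimeError("tree is not fitted")
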