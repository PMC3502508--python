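"""Chi-square binary decision tree over categorical amino-acid sites.

The tree works directly on the residue code (no numeric transformation):
each internal node bifurcates the sequences at one site into two disjoint
residue sets.  Candidate binary partitions at a site are generated by
ordering the residues observed at the node by their proportion of the
node's majority class and scanning all contiguous cut points; the partition
maximizing the chi-square statistic of the 2 x G branch-by-kingdom table is
adopted when its p-value passes the significance level and both branches
hold enough sequences.  Default settings: significance 0.20, depth limit 4,
minimum 10 observations to split, minimum 4 per leaf, and a purity stop
when a node is almost entirely one Kingdom.

At prediction time a sequence whose residue at a split site is a gap, or
was never observed at that node during training, is left UNCLASSIFIED.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.base import BaseEstimator, ClassifierMixin

from .alignment import AMINO_ACIDS, UNCLASSIFIED, EnumeratedAlignment


@dataclass
class TreeNode:
    """One node: class counts plus either a split or a leaf label."""

    counts: dict[str, int]
    label: str
    site: int | None = None
    left_set: list[str] | None = None
    right_set: list[str] | None = None
    chi2: float | None = None
    p_value: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.site is None

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        d = {"counts": self.counts, "label": self.label}
        if not self.is_leaf:
            d.update(
                site=self.site,
                left_set=self.left_set,
                right_set=self.right_set,
                chi2=self.chi2,
                p_value=self.p_value,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(counts=dict(d["counts"]), label=d["label"])
        if "site" in d:
            node.site = d["site"]
            node.left_set = list(d["left_set"])
            node.right_set = list(d["right_set"])
            node.chi2 = d["chi2"]
            node.p_value = d["p_value"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


def chi_square_2xg(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) and p for a 2 x G
    contingency table; zero-sum columns are dropped."""
    t = np.asarray(table, dtype=float)
    t = t[:, t.sum(axis=0) > 0]
    if t.shape[1] < 2 or (t.sum(axis=1) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = chi2_contingency(t, correction=False)
    return float(stat), float(p)


def _majority(counts: pd.Series) -> str:
    # deterministic: ties broken alphabetically
    top = counts[counts == counts.max()]
    return sorted(top.index)[0]


class ChiSquareKingdomTree(ClassifierMixin, BaseEstimator):
    """Binary chi-square decision tree on residue identities.

    Parameters
    ----------
    alpha : float
        Significance level required of a split's chi-square p-value.
    max_depth, min_split, min_leaf : int
        Structural limits: depth of the tree, minimum node size to
        attempt a split, minimum sequences per branch.
    purity_stop : float
        Stop splitting once the majority class fraction reaches this.

    Attributes
    ----------
    root_ : TreeNode
    classes_ : sorted class labels seen in training
    split_sites_ : sorted sites used anywhere in the tree
    """

    def __init__(
        self,
        alpha: float = 0.20,
        max_depth: int = 4,
        min_split: int = 10,
        min_leaf: int = 4,
        purity_stop: float = 0.95,
    ):
        self.alpha = alpha
        self.max_depth = max_depth
        self.min_split = min_split
        self.min_leaf = min_leaf
        self.purity_stop = purity_stop

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y) -> "ChiSquareKingdomTree":
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_leaf > self.min_split:
            raise ValueError("min_leaf must be <= min_split")
        R = X.fixed_residues() if isinstance(X, EnumeratedAlignment) else pd.DataFrame(X)
        if len(R) == 0:
            raise ValueError("empty training set")
        y = pd.Series(np.asarray(y, dtype=object), index=R.index)
        self.classes_ = np.array(sorted(pd.unique(y)))
        self.sites_ = list(R.columns)
        self.root_ = self._grow(R, y, depth=0)
        self.split_sites_ = sorted(self._collect_sites(self.root_))
        return self

    def _collect_sites(self, node: TreeNode) -> set:
        if node.is_leaf:
            return set()
        return {node.site} | self._collect_sites(node.left) | self._collect_sites(node.right)

    def _node_counts(self, y: pd.Series) -> dict[str, int]:
        vc = y.value_counts()
        return {str(c): int(vc.get(c, 0)) for c in self.classes_}

    def _grow(self, R: pd.DataFrame, y: pd.Series, depth: int) -> TreeNode:
        counts = y.value_counts()
        node = TreeNode(counts=self._node_counts(y), label=_majority(counts))
        n = len(y)
        if (
            depth >= self.max_depth
            or n < self.min_split
            or counts.max() / n >= self.purity_stop
        ):
            return node
        best = self.best_split(R, y)
        if best is None:
            return node
        site, left_set, right_set, stat, p = best
        col = R[site]
        in_left = col.isin(left_set)
        in_right = col.isin(right_set)
        node.site = int(site)
        node.left_set = sorted(left_set)
        node.right_set = sorted(right_set)
        node.chi2 = stat
        node.p_value = p
        node.left = self._grow(R[in_left], y[in_left], depth + 1)
        node.right = self._grow(R[in_right], y[in_right], depth + 1)
        return node

    def best_split(
        self, R: pd.DataFrame, y: pd.Series
    ) -> tuple[int, list[str], list[str], float, float] | None:
        """Best admissible (site, partition) by chi-square, or None.

        Ties on the statistic resolve to the lowest site index, then the
        earliest cut point.
        """
        if len(y) < self.min_split:
            return None
        major = _majority(y.value_counts())
        best = None
        for site in R.columns:
            col = R[site]
            ok = col.isin(list(AMINO_ACIDS))
            residues = col[ok]
            labels = y[ok]
            seen = pd.unique(residues)
            if len(seen) < 2:
                continue
            # order residues by their proportion of the node majority class
            stats_ = []
            for r in seen:
                sub = labels[residues == r]
                stats_.append((-(sub == major).mean(), str(r)))
            order = [r for _, r in sorted(stats_)]
            # class counts per residue, rows ordered as `order`
            ct = pd.crosstab(residues, labels).reindex(
                index=order, columns=self.classes_, fill_value=0
            )
            cum = ct.to_numpy().cumsum(axis=0)
            total = cum[-1]
            for c in range(1, len(order)):
                left_counts = cum[c - 1]
                right_counts = total - left_counts
                if left_counts.sum() < self.min_leaf or right_counts.sum() < self.min_leaf:
                    continue
                stat, p = chi_square_2xg(np.vstack([left_counts, right_counts]))
                if p > self.alpha:
                    continue
                key = (stat, -int(site), -c)
                if best is None or key > best[0]:
                    best = (key, int(site), order[:c], order[c:], stat, p)
        if best is None:
            return None
        _, site, left_set, right_set, stat, p = best
        return site, left_set, right_set, stat, p

    # -- prediction --------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        R = X.fixed_residues() if isinstance(X, EnumeratedAlignment) else pd.DataFrame(X)
        return np.array([self._route(row) for _, row in R.iterrows()], dtype=object)

    def _route(self, row: pd.Series) -> str:
        node = self.root_
        while not node.is_leaf:
            res = row.get(node.site)
            if res in node.left_set:
                node = node.left
            elif res in node.right_set:
                node = node.right
            else:  # gap or residue unseen at this node during training
                return UNCLASSIFIED
        return node.label

    # -- export ------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "params": self.get_params(),
            "classes": self.classes_.tolist(),
            "sites": [int(s) for s in self.sites_],
            "root": self.root_.to_dict(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "ChiSquareKingdomTree":
        model = cls(**d["params"])
        model.classes_ = np.array(d["classes"])
        model.sites_ = d["sites"]
        model.root_ = TreeNode.from_dict(d["root"])
        model.split_sites_ = sorted(model._collect_sites(model.root_))
        return model

    @classmethod
    def load(cls, path: str | Path) -> "ChiSquareKingdomTree":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def render_text(self) -> str:
        """Indented dichotomous-key rendering of the fitted tree."""
        lines: list[str] = []

        def walk(node: TreeNode, indent: int, prefix: str) -> None:
            pad = "  " * indent
            counts = ", ".join(f"{k}={v}" for k, v in node.counts.items())
            if node.is_leaf:
                lines.append(f"{pad}{prefix}-> {node.label}  [{counts}]")
            else:
                lines.append(
                    f"{pad}{prefix}site {node.site}  [{counts}]  "
                    f"(chi2={node.chi2:.1f}, p={node.p_value:.2g})"
                )
                walk(node.left, indent + 1, f"{{{''.join(node.left_set)}}} ")
                walk(node.right, indent + 1, f"{{{''.join(node.right_set)}}} ")

        walk(self.root_, 0, "")
        return "\n".join(lines)


def fit_tree(alignment, labels, **params) -> ChiSquareKingdomTree:
    return ChiSquareKingdomTree(**params).fit(alignment, labels)
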