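"""Depth-weighted prevalence (DWP) of signed feature sets in a tree ensemble.

A random root-to-leaf path of a tree is chosen by flipping a fair coin at
every internal node, so a path of depth D has probability 2^-D.  Along a path,
the *thresholded signed-feature set* F^eps collects (feature, branch sign)
pairs for internal nodes whose impurity decrease exceeds eps, keeping only
the first occurrence of each feature.  The DWP of a signed set S is the
probability that S appears inside F^eps of the random path, averaged over the
trees of the ensemble.

Rather than sampling paths, every leaf path is enumerated with its exact
2^-depth weight, so only tree randomness remains approximated (by the number
of trees).  Mining all signed sets above a support level is done with a
weighted FP-growth over the path transactions: support of a set is the summed
weight of the transactions containing it, which is exactly its DWP estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .forest import Forest
from .lss_model import SignedFeature

__all__ = [
    "PathTransaction",
    "DWPTable",
    "extract_transactions",
    "dwp_estimate",
    "mine_frequent",
    "fpgrowth_weighted",
]

_SLACK = 1e-12  # absolute slack on support comparisons


@dataclass(frozen=True)
class PathTransaction:
    """The signed-feature set of one root-to-leaf path with its path weight
    2^-depth / n_trees."""

    items: frozenset  # of SignedFeature
    weight: float
    tree_id: int
    leaf_id: int


@dataclass
class DWPTable:
    """Mined signed sets with their DWP estimates."""

    entries: dict  # frozenset[SignedFeature] -> float
    epsilon: float
    n_trees: int
    min_support: float | None = None
    smax: int | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def sorted_items(self) -> list:
        return sorted(self.entries.items(), key=lambda kv: (-kv[1], sorted(kv[0])))


def extract_transactions(forest: Forest, epsilon: float) -> list:
    """One transaction per (tree, leaf): signed features of nodes on the path
    with impurity decrease strictly above ``epsilon``, first occurrence per
    feature; weight 2^-depth / n_trees."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    out = []
    ntrees = forest.n_trees
    for ti, tree in enumerate(forest.trees):
        # per-node: does its split clear the threshold?
        above = {}
        for nid, node in tree.nodes.items():
            if node.is_leaf:
                continue
            l, r = tree.nodes[node.left], tree.nodes[node.right]
            n = node.n_samples
            di = node.impurity - (l.n_samples / n) * l.impurity - (r.n_samples / n) * r.impurity
            above[nid] = di > epsilon
        # DFS carrying the running first-occurrence item list
        stack = [(tree.root, 0, ())]
        while stack:
            nid, depth, items = stack.pop()
            node = tree.nodes[nid]
            if node.is_leaf:
                out.append(
                    PathTransaction(
                        items=frozenset(SignedFeature(k, b) for k, b in items),
                        weight=2.0 ** (-depth) / ntrees,
                        tree_id=ti,
                        leaf_id=nid,
                    )
                )
                continue
            if above[nid] and all(k != node.feature for k, _ in items):
                stack.append((node.right, depth + 1, items + ((node.feature, +1),)))
                stack.append((node.left, depth + 1, items + ((node.feature, -1),)))
            else:
                stack.append((node.right, depth + 1, items))
                stack.append((node.left, depth + 1, items))
    return out


def dwp_estimate(transactions: Sequence[PathTransaction], S: Iterable) -> float:
    """Summed weight of transactions containing S; the empty set has DWP 1."""
    if not transactions:
        raise ValueError("no transactions")
    S = frozenset(SignedFeature(int(k), int(b)) for k, b in S)
    return math.fsum(t.weight for t in transactions if S <= t.items)


# ---------------------------------------------------------------------------
# weighted FP-growth


class _FPNode:
    __slots__ = ("item", "weight", "parent", "children")

    def __init__(self, item, parent):
        self.item = item
        self.weight = 0.0
        self.parent = parent
        self.children = {}


def _build_fptree(weighted_transactions, item_order):
    root = _FPNode(None, None)
    node_links: dict = {item: [] for item in item_order}
    rank = {item: i for i, item in enumerate(item_order)}
    for items, w in weighted_transactions:
        cur = root
        for item in sorted((i for i in items if i in rank), key=rank.__getitem__):
            nxt = cur.children.get(item)
            if nxt is None:
                nxt = _FPNode(item, cur)
                cur.children[item] = nxt
                node_links[item].append(nxt)
            nxt.weight += w
            cur = nxt
    return node_links


def _mine(node_links, item_order, min_support, max_len, suffix, out):
    # iterate least-frequent first (reverse of the ordering used in the tree)
    for item in reversed(item_order):
        nodes = node_links[item]
        support = math.fsum(n.weight for n in nodes)
        if support < min_support - _SLACK:
            continue
        itemset = suffix | {item}
        out[frozenset(itemset)] = support
        if len(itemset) >= max_len:
            continue
        # conditional pattern base: prefix path of every node, carrying its weight
        cond = []
        for n in nodes:
            path = []
            cur = n.parent
            while cur.item is not None:
                path.append(cur.item)
                cur = cur.parent
            if path:
                cond.append((path, n.weight))
        if not cond:
            continue
        csup: dict = {}
        for path, w in cond:
            for it in path:
                csup[it] = csup.get(it, 0.0) + w
        corder = [it for it in item_order
                  if csup.get(it, 0.0) >= min_support - _SLACK]
        if not corder:
            continue
        clinks = _build_fptree(cond, corder)
        _mine(clinks, corder, min_support, max_len, itemset, out)


def fpgrowth_weighted(weighted_transactions: Sequence[tuple], min_support: float,
                      max_len: int) -> dict:
    """All itemsets of size <= max_len whose weighted support (summed weight of
    the transactions containing them) reaches ``min_support``.

    ``weighted_transactions`` is a sequence of (iterable-of-items, weight).
    Returns {frozenset(items): exact support}.  Generic over hashable items.
    """
    if not 0 < min_support:
        raise ValueError("min_support must be positive")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    tx = [(tuple(items), w) for items, w in weighted_transactions]
    supports: dict = {}
    for items, w in tx:
        for it in set(items):
            supports[it] = supports.get(it, 0.0) + w
    # order items by decreasing support (ties by repr) for a compact tree
    item_order = [it for it in sorted(supports, key=lambda i: (-supports[i], repr(i)))
                  if supports[it] >= min_support - _SLACK]
    if not item_order:
        return {}
    node_links = _build_fptree(tx, item_order)
    out: dict = {}
    _mine(node_links, item_order, min_support, max_len, frozenset(), out)
    # recompute supports with fsum over original transactions is not needed:
    # FP-tree weights are exact sums of transaction weights.
    return out


def mine_frequent(transactions: Sequence[PathTransaction], min_support: float,
                  smax: int, epsilon: float | None = None) -> DWPTable:
    """Signed sets of size <= smax with DWP estimate >= min_support.

    Support is anti-monotone under set inclusion (a superset appears in a
    subset of the transactions), so FP-growth enumerates exactly the sets
    above threshold together with their exact weighted supports.
    """
    if not 0 < min_support <= 1:
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    if smax < 1:
        raise ValueError("smax must be >= 1")
    wt = [(t.items, t.weight) for t in transactions]
    found = fpgrowth_weighted(wt, min_support, smax)
    ntrees = len({t.tree_id for t in transactions})
    return DWPTable(entries=found, epsilon=epsilon if epsilon is not None else math.nan,
                    n_trees=ntrees, min_support=min_support, smax=smax)


def dump_transactions(transactions: Sequence[PathTransaction], path: str | Path) -> None:
    """Tab-delimited dump: tree_id, leaf_id, weight, then "k:+1"/"k:-1" tokens."""
    lines = []
    for t in transactions:
        toks = [f"{f.index}:{f.sign:+d}" for f in sorted(t.items)]
        lines.append("\t".join([str(t.tree_id), str(t.leaf_id), f"{t.weight:.17g}", *toks]))
    Path(path).write_text("\n".join(lines) + "\n")
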