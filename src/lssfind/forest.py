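"""CART regression-tree ensembles with variance impurity.

Trees are grown greedily on the *full* dataset (no bootstrap): at every node a
random subset of ``mtry`` features is drawn without replacement and the
(feature, threshold) pair maximizing the impurity decrease

    dI(t) = I(t) - N(t_l)/N(t) * I(t_l) - N(t_r)/N(t) * I(t_r)

is taken, where I is the response variance in the node.  Candidate thresholds
are midpoints between consecutive distinct feature values; samples equal to
the threshold go left ("<=" branch).  Ties between splits are broken by the
smaller feature index, then the smaller threshold, so fits are reproducible
bit-for-bit given a seed.  Growth stops at pure nodes or when no split leaves
at least ``min_child`` samples on each side.

The ensemble representation is backend-neutral: an id-indexed node table per
tree, so ensembles fitted elsewhere (e.g. scikit-learn) can be imported and
mined identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .lss_model import Dataset

__all__ = [
    "TreeNode",
    "DecisionTree",
    "Forest",
    "impurity_decrease",
    "fit_forest",
    "import_forest",
    "from_sklearn",
    "build_illustrative_ensemble",
]

LEAF = -1  # feature marker for leaf nodes


@dataclass
class TreeNode:
    id: int
    feature: int  # 1-based split feature, or LEAF
    threshold: float
    n_samples: int
    impurity: float
    value: float
    left: int | None = None
    right: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature == LEAF


@dataclass
class DecisionTree:
    nodes: dict  # id -> TreeNode
    root: int = 0

    def __post_init__(self) -> None:
        self._check()

    def _check(self) -> None:
        if self.root not in self.nodes:
            raise ValueError(f"root id {self.root} not in node table")
        seen = set()
        parents: dict = {}
        stack = [self.root]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise ValueError(f"node {nid} reachable twice (not a tree)")
            seen.add(nid)
            node = self.nodes.get(nid)
            if node is None:
                raise ValueError(f"child id {nid} missing from node table")
            kids = (node.left, node.right)
            if node.is_leaf:
                if any(k is not None for k in kids):
                    raise ValueError(f"leaf node {nid} has children")
            else:
                if any(k is None for k in kids):
                    raise ValueError(f"internal node {nid} is missing a child")
                for k in kids:
                    if k in parents:
                        raise ValueError(f"node {k} has two parents")
                    parents[k] = nid
                stack.extend(kids)
        orphans = set(self.nodes) - seen
        if orphans:
            raise ValueError(f"orphan nodes not reachable from root: {sorted(orphans)}")

    def leaves(self) -> Iterator[TreeNode]:
        return (n for n in self.nodes.values() if n.is_leaf)

    def paths(self) -> Iterator[tuple]:
        """Yield (leaf_id, depth, [(node, sign), ...]) for every root-to-leaf
        path; sign is -1 when the path takes the left ("<=") branch at that
        internal node, +1 for the right branch."""
        stack = [(self.root, [])]
        while stack:
            nid, trail = stack.pop()
            node = self.nodes[nid]
            if node.is_leaf:
                yield nid, len(trail), trail
            else:
                stack.append((node.right, trail + [(node, +1)]))
                stack.append((node.left, trail + [(node, -1)]))

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf id for each row of X."""
        out = np.empty(X.shape[0], dtype=int)
        for i, x in enumerate(np.asarray(X, dtype=float)):
            node = self.nodes[self.root]
            while not node.is_leaf:
                node = self.nodes[node.left if x[node.feature - 1] <= node.threshold else node.right]
            out[i] = node.id
        return out


@dataclass
class Forest:
    trees: list  # of DecisionTree
    p: int
    mtry: int | None = None
    seed: int | None = None
    impurity: str = "variance"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.trees) < 1:
            raise ValueError("a forest needs at least one tree")
        for t in self.trees:
            for node in t.nodes.values():
                if not node.is_leaf and not 1 <= node.feature <= self.p:
                    raise ValueError(f"node {node.id} splits on feature {node.feature} outside 1..{self.p}")

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        acc = np.zeros(X.shape[0])
        for t in self.trees:
            leaf_ids = t.apply(X)
            acc += np.array([t.nodes[i].value for i in leaf_ids])
        return acc / self.n_trees

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "meta": {"p": self.p, "n_trees": self.n_trees, "mtry": self.mtry,
                     "seed": self.seed, "impurity": self.impurity, **self.meta},
            "trees": [
                {
                    "root": t.root,
                    "nodes": [
                        {
                            "id": n.id, "feature": n.feature,
                            "threshold": None if n.is_leaf else float(f"{n.threshold:.17g}"),
                            "n_samples": n.n_samples, "impurity": n.impurity,
                            "value": n.value, "left": n.left, "right": n.right,
                        }
                        for n in sorted(t.nodes.values(), key=lambda n: n.id)
                    ],
                }
                for t in self.trees
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "Forest":
        return import_forest(json.loads(Path(path).read_text()))


def impurity_decrease(tree: DecisionTree, node_id: int) -> float:
    """Variance-impurity decrease at an internal node from the stored node
    statistics; nonnegative up to floating-point slack."""
    node = tree.nodes[node_id]
    if node.is_leaf:
        raise ValueError(f"node {node_id} is a leaf; impurity decrease undefined")
    l, r = tree.nodes[node.left], tree.nodes[node.right]
    n = node.n_samples
    return node.impurity - (l.n_samples / n) * l.impurity - (r.n_samples / n) * r.impurity


# ---------------------------------------------------------------------------
# fitting

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (a and callable(a[0])) else a[0]


@njit(cache=True)
def _grow_tree_arrays(X, y, mtry, min_child, seed):
    """Grow one CART tree; returns parallel node arrays.

    Candidate features are drawn without replacement per node and scanned in
    ascending index order with a strictly-greater gain comparison, so ties go
    to the smallest feature index and then the smallest threshold.  Gains are
    SSE reductions (n_node * impurity decrease).
    """
    np.random.seed(seed)
    n, p = X.shape
    cap = 2 * n + 1
    feature = np.full(cap, -1, np.int64)
    thresh = np.full(cap, np.nan)
    left = np.full(cap, -1, np.int64)
    right = np.full(cap, -1, np.int64)
    nsamp = np.zeros(cap, np.int64)
    imp = np.zeros(cap)
    val = np.zeros(cap)

    idx = np.arange(n)
    xs = np.empty(n)
    ys = np.empty(n)
    pool = np.empty(p, np.int64)
    feats = np.empty(mtry, np.int64)

    # node stats at creation
    tot = 0.0
    tot2 = 0.0
    for i in range(n):
        tot += y[i]
        tot2 += y[i] * y[i]
    nsamp[0] = n
    val[0] = tot / n
    iv = tot2 / n - val[0] * val[0]
    imp[0] = iv if iv > 0.0 else 0.0
    node_count = 1

    stack_node = np.empty(cap, np.int64)
    stack_lo = np.empty(cap, np.int64)
    stack_hi = np.empty(cap, np.int64)
    stack_node[0], stack_lo[0], stack_hi[0] = 0, 0, n
    sp = 1
    while sp > 0:
        sp -= 1
        nid, lo, hi = stack_node[sp], stack_lo[sp], stack_hi[sp]
        m = hi - lo
        if m < 2 * min_child or imp[nid] <= 1e-15:
            continue
        # mtry features without replacement (partial Fisher-Yates), ascending
        for j in range(p):
            pool[j] = j
        for j in range(mtry):
            r = j + np.random.randint(0, p - j)
            pool[j], pool[r] = pool[r], pool[j]
        feats[:] = np.sort(pool[:mtry])

        tot = 0.0
        tot2 = 0.0
        for i in range(lo, hi):
            v = y[idx[i]]
            tot += v
            tot2 += v * v
        sse_t = tot2 - tot * tot / m

        best_gain = 0.0
        best_f = -1
        best_thr = 0.0
        for fj in range(mtry):
            f = feats[fj]
            for i in range(m):
                xs[i] = X[idx[lo + i], f]
                ys[i] = y[idx[lo + i]]
            order = np.argsort(xs[:m])
            sl = 0.0
            sl2 = 0.0
            for i in range(1, m):
                v = ys[order[i - 1]]
                sl += v
                sl2 += v * v
                xl = xs[order[i - 1]]
                xr = xs[order[i]]
                if xl >= xr:
                    continue
                if i < min_child or m - i < min_child:
                    continue
                gain = sse_t - (sl2 - sl * sl / i) - ((tot2 - sl2) - (tot - sl) * (tot - sl) / (m - i))
                if gain > best_gain:
                    best_gain = gain
                    best_f = f
                    best_thr = 0.5 * (xl + xr)
        if best_f < 0:
            continue

        # in-place partition of idx[lo:hi] by x <= threshold
        i, j = lo, hi - 1
        while i <= j:
            if X[idx[i], best_f] <= best_thr:
                i += 1
            else:
                idx[i], idx[j] = idx[j], idx[i]
                j -= 1
        mid = i
        lid, rid = node_count, node_count + 1
        node_count += 2
        feature[nid] = best_f + 1  # 1-based on the outside
        thresh[nid] = best_thr
        left[nid], right[nid] = lid, rid
        for cid, clo, chi in ((lid, lo, mid), (rid, mid, hi)):
            ct = 0.0
            ct2 = 0.0
            for i in range(clo, chi):
                v = y[idx[i]]
                ct += v
                ct2 += v * v
            cn = chi - clo
            nsamp[cid] = cn
            val[cid] = ct / cn
            civ = ct2 / cn - val[cid] * val[cid]
            imp[cid] = civ if civ > 0.0 else 0.0
            stack_node[sp], stack_lo[sp], stack_hi[sp] = cid, clo, chi
            sp += 1
    return feature[:node_count], thresh[:node_count], left[:node_count], \
        right[:node_count], nsamp[:node_count], imp[:node_count], val[:node_count]


def _grow_tree(X: np.ndarray, y: np.ndarray, mtry: int, seed: int,
               min_child: int) -> DecisionTree:
    feature, thresh, left, right, nsamp, imp, val = _grow_tree_arrays(
        X, y, mtry, min_child, seed
    )
    nodes = {
        i: TreeNode(
            id=i, feature=int(feature[i]) if feature[i] > 0 else LEAF,
            threshold=float(thresh[i]), n_samples=int(nsamp[i]),
            impurity=float(imp[i]), value=float(val[i]),
            left=int(left[i]) if left[i] >= 0 else None,
            right=int(right[i]) if right[i] >= 0 else None,
        )
        for i in range(len(feature))
    }
    return DecisionTree(nodes=nodes, root=0)


def fit_forest(data: Dataset, n_trees: int = 100, mtry: int | None = None,
               seed: int | None = None, min_child: int = 1) -> Forest:
    """Grow ``n_trees`` CART trees on the full dataset (no bootstrap).

    mtry defaults to ceil(p/2), the theoretically favored subsampling rate
    when signal features are few relative to p.  Trees differ only through the
    per-node feature subsampling stream, which is derived deterministically
    from ``seed``.
    """
    X, y = data.X, data.y
    p = X.shape[1]
    if mtry is None:
        mtry = math.ceil(p / 2)
    if not 1 <= mtry <= p:
        raise ValueError(f"mtry must be in [1, {p}], got {mtry}")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to fit")
    ss = np.random.SeedSequence(seed)
    tree_seeds = [int(s) for s in ss.generate_state(n_trees) % (2**31)]
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    trees = [_grow_tree(X, y, mtry, ts, min_child) for ts in tree_seeds]
    return Forest(trees=trees, p=p, mtry=mtry, seed=seed,
                  meta={"min_child": min_child, "n": X.shape[0]})


# ---------------------------------------------------------------------------
# import / export


def import_forest(obj: dict) -> Forest:
    """Build a Forest from the generic node-table export schema, validating
    every tree invariant; raises naming the offending node id."""
    meta = obj.get("meta", {})
    trees = []
    for td in obj["trees"]:
        nodes = {}
        for nd in td["nodes"]:
            nodes[int(nd["id"])] = TreeNode(
                id=int(nd["id"]), feature=int(nd["feature"]),
                threshold=float(nd["threshold"]) if nd["threshold"] is not None else math.nan,
                n_samples=int(nd["n_samples"]), impurity=float(nd["impurity"]),
                value=float(nd["value"]),
                left=None if nd.get("left") is None else int(nd["left"]),
                right=None if nd.get("right") is None else int(nd["right"]),
            )
        trees.append(DecisionTree(nodes=nodes, root=int(td.get("root", 0))))
    p = int(meta.get("p") or max(
        (n.feature for t in trees for n in t.nodes.values() if not n.is_leaf),
        default=1,
    ))
    return Forest(trees=trees, p=p, mtry=meta.get("mtry"), seed=meta.get("seed"),
                  meta={k: v for k, v in meta.items()
                        if k not in ("p", "n_trees", "mtry", "seed", "impurity")})


def from_sklearn(rf, p: int | None = None) -> Forest:
    """Convert a fitted sklearn RandomForestRegressor (or list of estimators)
    into the native representation; feature indices shift to 1-based."""
    estimators = getattr(rf, "estimators_", rf)
    trees = []
    p_seen = 0
    for est in estimators:
        t = est.tree_
        nodes = {}
        for nid in range(t.node_count):
            leaf = t.children_left[nid] == -1
            feat = LEAF if leaf else int(t.feature[nid]) + 1
            p_seen = max(p_seen, 0 if leaf else feat)
            nodes[nid] = TreeNode(
                id=nid, feature=feat,
                threshold=math.nan if leaf else float(t.threshold[nid]),
                n_samples=int(t.n_node_samples[nid]),
                impurity=float(t.impurity[nid]),
                value=float(t.value[nid].ravel()[0]),
                left=None if leaf else int(t.children_left[nid]),
                right=None if leaf else int(t.children_right[nid]),
            )
        trees.append(DecisionTree(nodes=nodes, root=0))
    return Forest(trees=trees, p=p or p_seen, mtry=getattr(rf, "max_features", None)
                  if isinstance(getattr(rf, "max_features", None), int) else None)


# ---------------------------------------------------------------------------
# the two-tree population ensemble for E[Y|X] = 1(X1<=0.5) 1(X2<=0.5)


def build_illustrative_ensemble(nominal_n: int = 1000) -> Forest:
    """The exact population tree pair for the two-feature conjunction model.

    Tree A splits feature 1 at 0.5 at the root; its right child (X1 > 0.5) is
    a pure 0-leaf, its left child splits feature 2 at 0.5 into a 1-leaf and a
    0-leaf.  Tree B mirrors with the features swapped.  Node impurities are
    the population variances (root 3/16, inner 1/4, leaves 0), so the root
    impurity decrease is exactly 1/16 and the inner one 1/4; sample counts
    are the population region probabilities scaled by ``nominal_n``.
    """

    def tree(first: int, second: int) -> DecisionTree:
        n = nominal_n
        nodes = {
            0: TreeNode(0, first, 0.5, n, 3 / 16, 0.25, left=1, right=2),
            1: TreeNode(1, second, 0.5, n // 2, 1 / 4, 0.5, left=3, right=4),
            2: TreeNode(2, LEAF, math.nan, n // 2, 0.0, 0.0),
            3: TreeNode(3, LEAF, math.nan, n // 4, 0.0, 1.0),
            4: TreeNode(4, LEAF, math.nan, n // 4, 0.0, 0.0),
        }
        return DecisionTree(nodes=nodes, root=0)

    return Forest(trees=[tree(1, 2), tree(2, 1)], p=2, mtry=2,
                  meta={"population": True, "nominal_n": nominal_n})
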