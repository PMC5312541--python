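"""Ultrametric tree data model, pure-birth simulation, shape statistics, Newick I/O.

The central object is :class:`Chronogram`, a rooted ultrametric tree whose node
*ages* (time before present) are the canonical representation; branch lengths
are always derived as ``age(parent) - age(child)``, so the two can never drift
apart. Polytomies are allowed everywhere except where an operation explicitly
requires a binary tree (gamma statistic, Colless index).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import dendropy

__all__ = [
    "Chronogram",
    "TreeError",
    "simulate_pure_birth",
    "gamma_statistic",
    "colless_index",
    "branch_length_sd",
    "read_newick",
    "write_newick",
]

#: relative tolerance (times tree height) within which tip ages must be zero
ULTRAMETRIC_RTOL = 1e-8


class TreeError(ValueError):
    """Invalid tree structure or malformed Newick input."""


class Chronogram:
    """Rooted ultrametric tree with node ages in time units.

    Parameters
    ----------
    parent : array of int
        ``parent[i]`` is the index of node *i*'s parent; the root has -1.
    age : array of float
        Age of each node, measured as time before present; tips have age 0
        (within ``ULTRAMETRIC_RTOL * height``, and are snapped to exactly 0),
        the root has age equal to the tree height.
    labels : sequence of str or None, optional
        Node labels; tips must carry unique non-empty labels, internal labels
        are optional and preserved through Newick round-trips.
    validate : bool
        Check all structural invariants at construction (default). Trees that
        fail ultrametricity are rejected, never silently repaired.
    """

    __slots__ = ("parent", "age", "labels", "children", "root", "tips",
                 "height", "_postorder")

    def __init__(self, parent, age, labels=None, validate: bool = True):
        self.parent = np.asarray(parent, dtype=np.int64).copy()
        self.age = np.asarray(age, dtype=float).copy()
        n = self.parent.shape[0]
        if self.age.shape[0] != n:
            raise TreeError("parent and age arrays differ in length")
        if labels is None:
            labels = [None] * n
        if len(labels) != n:
            raise TreeError("labels length mismatch")
        self.labels = list(labels)

        children: list[list[int]] = [[] for _ in range(n)]
        root = -1
        for i in range(n):
            p = int(self.parent[i])
            if p == i:
                raise TreeError(f"node {i} is its own parent")
            if p < 0:
                if root >= 0:
                    raise TreeError("more than one root")
                root = i
            else:
                if p >= n:
                    raise TreeError(f"parent index {p} out of range")
                children[p].append(i)
        if root < 0:
            raise TreeError("no root found")
        self.children = children
        self.root = root
        self.tips = np.array([i for i in range(n) if not children[i]],
                             dtype=np.int64)
        self.height = float(self.age[root])
        self._postorder: np.ndarray | None = None
        if validate:
            self._validate()

    # ------------------------------------------------------------------ #
    # structure

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def n_tips(self) -> int:
        return self.tips.shape[0]

    @property
    def n_internal(self) -> int:
        return self.n_nodes - self.n_tips

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips]

    @property
    def is_binary(self) -> bool:
        return all(len(c) == 2 for c in self.children if c)

    def internal_nodes(self, include_root: bool = True) -> np.ndarray:
        out = [i for i in range(self.n_nodes) if self.children[i]]
        if not include_root:
            out = [i for i in out if i != self.root]
        return np.array(out, dtype=np.int64)

    def postorder(self) -> np.ndarray:
        """Node indices in postorder (children before parents)."""
        if self._postorder is None:
            order = []
            stack = [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(self.children[v])
            self._postorder = np.array(order[::-1], dtype=np.int64)
        return self._postorder

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1]

    @property
    def branch_lengths(self) -> np.ndarray:
        """Branch lengths of all non-root nodes, derived from ages."""
        mask = np.arange(self.n_nodes) != self.root
        idx = np.arange(self.n_nodes)[mask]
        return self.age[self.parent[idx]] - self.age[idx]

    def copy(self) -> "Chronogram":
        return Chronogram(self.parent, self.age, self.labels, validate=False)

    # ------------------------------------------------------------------ #
    # validation

    def _validate(self) -> None:
        n = self.n_nodes
        if self.n_tips < 2:
            raise TreeError("tree must have at least 2 tips")
        order = self.postorder()
        if order.shape[0] != n:
            raise TreeError("tree is not connected (unreachable nodes)")
        H = self.height
        if not (H > 0 and math.isfinite(H)):
            raise TreeError(f"invalid tree height {H}")
        tol = ULTRAMETRIC_RTOL * H
        tip_ages = self.age[self.tips]
        if np.any(np.abs(tip_ages) > tol):
            worst = float(np.max(np.abs(tip_ages)))
            raise TreeError(
                f"tree is not ultrametric: tip age deviates by {worst:g} "
                f"(tolerance {tol:g})")
        self.age[self.tips] = 0.0
        for i in range(n):
            p = int(self.parent[i])
            if p < 0:
                continue
            if self.age[p] < self.age[i] - 1e-12 * H:
                raise TreeError(
                    f"age(parent) < age(child) on edge {p}->{i}: "
                    f"{self.age[p]:g} < {self.age[i]:g}")
        for t in self.tips:
            if self.age[self.parent[t]] <= 0:
                raise TreeError(f"tip {self.labels[t]!r} has a non-positive "
                                "terminal branch length")
        labels = self.tip_labels
        if any(l is None or l == "" for l in labels):
            raise TreeError("all tips must carry non-empty labels")
        if len(set(labels)) != len(labels):
            raise TreeError("tip labels are not unique")

    # ------------------------------------------------------------------ #
    # Newick I/O

    @classmethod
    def from_newick(cls, text: str) -> "Chronogram":
        """Parse a Newick string (branch lengths mandatory, polytomies OK)."""
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"malformed Newick: {exc}") from exc
        dnodes = list(dtree.preorder_node_iter())
        if len(dnodes) < 3:
            raise TreeError("tree must have at least 2 tips")
        index = {id(nd): i for i, nd in enumerate(dnodes)}
        n = len(dnodes)
        parent = np.full(n, -1, dtype=np.int64)
        depth = np.zeros(n)
        blen = np.zeros(n)
        labels: list[str | None] = [None] * n
        for i, nd in enumerate(dnodes):
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    raise TreeError("branch lengths are mandatory in Newick "
                                    "input (missing edge length)")
                p = index[id(nd.parent_node)]
                parent[i] = p
                blen[i] = float(nd.edge.length)
                depth[i] = depth[p] + blen[i]
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label:
                labels[i] = nd.label
        # ages propagate top-down from the root (age = max tip depth) so a
        # write -> read -> write cycle reaches a bit-exact fixed point
        age = np.zeros(n)
        age[0] = float(depth.max())
        for i in range(1, n):
            age[i] = age[parent[i]] - blen[i]
        return cls(parent, age, labels)

    def to_newick(self) -> str:
        """Serialize to Newick; branch lengths use the shortest decimal
        representation that round-trips the double bit-exactly (never less
        precise than 12 significant digits requires)."""
        parts: dict[int, str] = {}
        for v in self.postorder():
            v = int(v)
            kids = self.children[v]
            if kids:
                inner = ",".join(parts[c] for c in kids)
                lab = self.labels[v]
                s = f"({inner}){lab if lab else ''}"
            else:
                s = _quote_label(self.labels[v])
            if v != self.root:
                bl = self.age[self.parent[v]] - self.age[v]
                s += f":{float(bl)!r}"
            parts[v] = s
        return parts[self.root] + ";"


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "():,;[]' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_newick(text: str) -> Chronogram:
    """Parse Newick text into a :class:`Chronogram` (see ``from_newick``)."""
    return Chronogram.from_newick(text)


def write_newick(tree: Chronogram) -> str:
    """Serialize a :class:`Chronogram` to Newick text."""
    return tree.to_newick()


# ---------------------------------------------------------------------- #
# simulation


def simulate_pure_birth(n_tips: int, birth_rate: float = 1.0,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None) -> Chronogram:
    """Simulate a pure-birth (Yule) ultrametric chronogram with ``n_tips`` tips.

    The process starts from two lineages at the root. While fewer than
    ``n_tips`` lineages exist, the waiting time to the next birth is drawn
    exponentially with rate ``birth_rate * k`` (k = current lineage count) and
    the splitting lineage is chosen uniformly. After the birth event that
    creates the n-th lineage, all lineages are extended by one further
    exponential waiting time with rate ``birth_rate * n_tips`` so terminal
    branches are strictly positive and all tips are contemporaneous. Heights
    are not rescaled.

    Parameters
    ----------
    n_tips : int
        Number of tips (>= 3).
    birth_rate : float
        Per-lineage speciation rate (> 0, events per time unit).
    seed, rng
        Either an integer seed or an existing numpy Generator.
    """
    if n_tips < 3:
        raise ValueError(f"n_tips must be >= 3, got {n_tips}")
    if not birth_rate > 0:
        raise ValueError(f"birth_rate must be positive, got {birth_rate}")
    if rng is None:
        rng = np.random.default_rng(seed)

    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    btime = np.zeros(n_nodes)  # time of node, forward from root at 0
    labels: list[str | None] = [None] * n_nodes

    t = 0.0
    nxt = 1                     # node 0 is the root
    active = [0, 0]             # parent node of each open lineage
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        j = int(rng.integers(k))
        v = nxt
        nxt += 1
        parent[v] = active[j]
        btime[v] = t
        active[j] = v
        active.append(v)
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for m, pa in enumerate(active):
        v = nxt
        nxt += 1
        parent[v] = pa
        btime[v] = t
        labels[v] = f"t{m + 1}"

    age = t - btime
    return Chronogram(parent, age, labels)


# ---------------------------------------------------------------------- #
# shape statistics


def gamma_statistic(tree: Chronogram) -> float:
    """Pybus-Harvey gamma statistic of a binary ultrametric tree.

    With ``g_k`` the duration during which exactly k lineages exist
    (k = 2..n), ``T = sum_j j*g_j`` and ``T_i = sum_{j<=i} j*g_j``::

        gamma = [mean_{i=2..n-1}(T_i) - T/2] / [T * sqrt(1 / (12 (n-2)))]

    Under the pure-birth model gamma is asymptotically standard normal;
    negative values indicate "tippy" trees, positive values "stemmy" trees.
    """
    if not tree.is_binary:
        raise TreeError("gamma statistic requires a fully binary tree")
    n = tree.n_tips
    if n < 3:
        raise TreeError("gamma statistic requires at least 3 tips")
    t_int = np.sort(tree.age[tree.internal_nodes()])[::-1]  # t_1=H .. t_{n-1}
    g = np.empty(n - 1)          # g[i] is g_{i+2}
    g[:-1] = t_int[:-1] - t_int[1:]
    g[-1] = t_int[-1]
    k = np.arange(2, n + 1, dtype=float)
    jg = k * g
    T = jg.sum()
    Ti = np.cumsum(jg)[:-1]      # T_2 .. T_{n-1}
    return float((Ti.mean() - T / 2.0) / (T * math.sqrt(1.0 / (12 * (n - 2)))))


def colless_index(tree: Chronogram) -> int:
    """Colless imbalance index: sum over internal nodes of |n_L - n_R|.

    Defined only for binary rooted trees; 0 for a fully balanced tree,
    (n-1)(n-2)/2 for the n-tip caterpillar.
    """
    if not tree.is_binary:
        raise TreeError("Colless index requires a fully binary tree")
    counts = np.zeros(tree.n_nodes, dtype=np.int64)
    total = 0
    for v in tree.postorder():
        v = int(v)
        kids = tree.children[v]
        if not kids:
            counts[v] = 1
        else:
            l, r = kids
            counts[v] = counts[l] + counts[r]
            total += abs(int(counts[l]) - int(counts[r]))
    return total


def branch_length_sd(tree: Chronogram) -> float:
    """Sample standard deviation (ddof=1) of all branch lengths.

    The root carries no edge in this representation, so no root edge is
    included. Requires at least two edges.
    """
    bl = tree.branch_lengths
    if bl.shape[0] < 2:
        raise TreeError("branch_length_sd requires at least 2 edges")
    return float(np.std(bl, ddof=1))
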