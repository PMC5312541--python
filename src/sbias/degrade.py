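"""Tree degradation: polytomy induction and BLADJ-style pseudo-chronograms.

Two families of degraded trees are produced from a "true" chronogram:

* **Polytomic chronograms** — a fraction of internal nodes is collapsed
  (deleted, children re-attached to the parent) under one of two strategies:
  ``shallow`` (only nodes in the tipward half of the tree, age < H/2,
  emulating the dense terminal polytomies of taxonomy-grafted supertrees) or
  ``all`` (every internal non-root node eligible). Ages of surviving nodes
  are untouched, so the result stays ultrametric with identical height and
  tip set.

* **Pseudo-chronograms** — the tree topology is kept but all node ages are
  discarded except for a small calibrated subset (plus the root), and the
  undated nodes are re-aged by even interpolation between the dated ones, in
  the manner of the BLADJ branch-length adjuster. The calibrated subset is
  drawn proportionally from five equal time-slices with a minimum of one node
  per non-empty slice.

The combination (shallow collapse applied to a pseudo-chronogram) probes the
interaction of the two defects.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .treespace import Chronogram, TreeError

__all__ = [
    "CollapseSpec",
    "FixedAgeSet",
    "collapse_nodes",
    "select_fixed_nodes",
    "bladj_calibrate",
    "make_polytomic_pseudochronogram",
]

logger = logging.getLogger(__name__)

STRATEGIES = ("shallow", "all")


def _round_half_away(x: float) -> int:
    """round-half-away-from-zero, platform-independent (x >= 0 here)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CollapseSpec:
    """Node-collapsing treatment: strategy, fraction of eligible nodes, seed."""
    strategy: str = "shallow"
    fraction: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}, "
                             f"got {self.strategy!r}")
        if not (0.0 <= self.fraction < 1.0):
            raise ValueError(f"fraction must be in [0, 1), got {self.fraction}")


@dataclass
class FixedAgeSet:
    """Node-index -> age constraints for calibration; the root is always present."""
    ages: dict[int, float]
    root: int

    def __post_init__(self):
        if self.root not in self.ages:
            raise ValueError("FixedAgeSet must contain the root")

    def __len__(self) -> int:
        return len(self.ages)

    def __contains__(self, node: int) -> bool:
        return node in self.ages


def collapse_nodes(tree: Chronogram, spec: CollapseSpec,
                   rng: np.random.Generator | None = None,
                   eligible_side: str = "tipward",
                   protect: set[int] | frozenset[int] = frozenset(),
                   ) -> Chronogram:
    """Collapse a random fraction of internal nodes into polytomies.

    Eligible nodes are internal non-root nodes with age < H/2 (``shallow``
    strategy, ``eligible_side="tipward"``; use ``"rootward"`` for the
    age > H/2 reading) or all internal non-root nodes (``all`` strategy).
    ``k = round(fraction * |eligible|)`` nodes are drawn uniformly without
    replacement; each is deleted and its children re-attached to its nearest
    surviving ancestor. Every surviving node keeps its original age, so the
    output is ultrametric with the input's height and tip set.

    ``protect`` removes specific node indices from eligibility (used by the
    combined treatment so calibrated nodes are never collapsed).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if eligible_side not in ("tipward", "rootward"):
        raise ValueError("eligible_side must be 'tipward' or 'rootward'")

    internal = [int(v) for v in tree.internal_nodes(include_root=False)]
    if spec.strategy == "shallow":
        half = tree.height / 2.0
        if eligible_side == "tipward":
            eligible = [v for v in internal if tree.age[v] < half]
        else:
            eligible = [v for v in internal if tree.age[v] > half]
    else:
        eligible = internal
    eligible = [v for v in eligible if v not in protect]

    k = _round_half_away(spec.fraction * len(eligible))
    if k == 0:
        return tree.copy()
    chosen = rng.choice(len(eligible), size=k, replace=False)
    removed = {eligible[int(i)] for i in chosen}

    keep = [v for v in range(tree.n_nodes) if v not in removed]
    new_index = {v: i for i, v in enumerate(keep)}
    parent = np.empty(len(keep), dtype=np.int64)
    for i, v in enumerate(keep):
        p = int(tree.parent[v])
        while p >= 0 and p in removed:
            p = int(tree.parent[p])
        parent[i] = new_index[p] if p >= 0 else -1
    age = tree.age[keep]
    labels = [tree.labels[v] for v in keep]
    return Chronogram(parent, age, labels)


def select_fixed_nodes(tree: Chronogram, fraction: float,
                       n_slices: int = 5,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None) -> FixedAgeSet:
    """Pick calibration nodes stratified over equal time-slices.

    ``[0, H]`` is partitioned into ``n_slices`` equal age intervals. The
    target total is ``m = round(fraction * #internal-non-root-nodes)``;
    per-slice quotas are proportional to per-slice node counts
    (largest-remainder rounding), raised to 1 for every non-empty slice. If
    the minimum-1 rule pushes the total above ``m``, quotas above 1 in the
    largest slices absorb the excess. Nodes are drawn uniformly within
    slices; the root is added with its true age and not counted in ``m``.
    """
    if not fraction > 0:
        raise ValueError(f"fraction must be > 0, got {fraction}")
    if fraction > 1:
        raise ValueError(f"fraction must be <= 1, got {fraction}")
    if rng is None:
        rng = np.random.default_rng(seed)

    internal = [int(v) for v in tree.internal_nodes(include_root=False)]
    if len(internal) < n_slices:
        raise TreeError(f"tree needs >= {n_slices} internal non-root nodes")
    H = tree.height
    width = H / n_slices
    slices: list[list[int]] = [[] for _ in range(n_slices)]
    for v in internal:
        s = min(int(tree.age[v] / width), n_slices - 1)
        slices[s].append(v)

    m = _round_half_away(fraction * len(internal))
    counts = np.array([len(s) for s in slices], dtype=float)
    nonempty = counts > 0
    m = max(m, int(nonempty.sum()))  # cannot fix fewer than 1 per non-empty slice

    # largest-remainder allocation proportional to slice sizes
    raw = m * counts / counts.sum()
    quota = np.floor(raw).astype(int)
    rem = raw - quota
    for i in np.argsort(-rem)[: m - quota.sum()]:
        quota[i] += 1
    # minimum one per non-empty slice
    quota[nonempty & (quota == 0)] = 1
    # absorb any excess from the largest slices (never below 1)
    order = np.argsort(-counts)
    while quota.sum() > m:
        changed = False
        for i in order:
            if quota.sum() == m:
                break
            if quota[i] > 1:
                quota[i] -= 1
                changed = True
        if not changed:
            break  # all quotas at 1; total stays above m
    quota = np.minimum(quota, counts.astype(int))

    ages: dict[int, float] = {tree.root: tree.height}
    for s, q in zip(slices, quota):
        if q > 0:
            picked = rng.choice(len(s), size=int(q), replace=False)
            for i in picked:
                v = s[int(i)]
                ages[v] = float(tree.age[v])
    return FixedAgeSet(ages=ages, root=tree.root)


def bladj_calibrate(topology: Chronogram, fixed: FixedAgeSet,
                    eps_rel: float = 1e-9) -> Chronogram:
    """Re-age a topology from a sparse set of fixed node ages, BLADJ-style.

    Tips are dated at age 0 by convention and the fixed nodes (always
    including the root) keep their exact ages. Every undated internal node
    ``v`` is placed by even interpolation: with ``A`` its nearest fixed
    ancestor (age ``t_A``, ``d_A`` edges away) and ``B`` the fixed node or
    tip below ``v`` minimizing the per-edge age drop
    ``(t_A - t_B) / (d_A + d_B)`` (search stops at fixed nodes; ties broken
    by smaller ``t_B``, then node index)::

        age(v) = t_A - d_A * (t_A - t_B) / (d_A + d_B)

    The minimum-slope choice of ``B`` spaces the longest undated chain
    through ``v`` evenly and guarantees ``age(v)`` never falls below any
    fixed descendant of ``v``. A final monotonicity pass enforces
    ``age(parent) >= age(child) + eps`` (eps = ``eps_rel * H``) by clamping
    undated children downward; every clamp is logged.
    """
    H = fixed.ages[fixed.root]
    n = topology.n_nodes
    age = np.zeros(n)
    is_fixed = np.zeros(n, dtype=bool)
    for v, a in fixed.ages.items():
        if not topology.children[v]:
            raise TreeError(f"fixed node {v} is a tip")
        if not (0.0 <= a <= H):
            raise TreeError(f"fixed age {a} outside [0, {H}]")
        age[v] = a
        is_fixed[v] = True

    # fixed-vs-fixed consistency along ancestor chains
    for v in fixed.ages:
        p = int(topology.parent[v])
        while p >= 0 and not is_fixed[p]:
            p = int(topology.parent[p])
        if p >= 0 and fixed.ages[p] <= fixed.ages[v]:
            raise TreeError(
                f"fixed ages violate ancestor ordering: node {p} "
                f"(age {fixed.ages[p]}) is an ancestor of node {v} "
                f"(age {fixed.ages[v]})")

    dated = is_fixed.copy()
    dated[topology.tips] = True  # tips at age 0

    # nearest fixed ancestor (age, edge distance), computed in preorder
    anc_age = np.zeros(n)
    anc_dist = np.zeros(n, dtype=np.int64)
    for v in topology.preorder():
        v = int(v)
        if v == topology.root:
            anc_age[v] = age[v] if is_fixed[v] else H
            continue
        p = int(topology.parent[v])
        if is_fixed[p]:
            anc_age[v], anc_dist[v] = age[p], 1
        else:
            anc_age[v], anc_dist[v] = anc_age[p], anc_dist[p] + 1

    undated = [int(v) for v in topology.internal_nodes() if not dated[v]]
    for v in undated:
        t_a, d_a = anc_age[v], int(anc_dist[v])
        best = None  # (slope, t_b, node)
        queue = deque([(c, 1) for c in topology.children[v]])
        while queue:
            w, d = queue.popleft()
            if dated[w]:
                slope = (t_a - age[w]) / (d_a + d)
                key = (slope, age[w], w)
                if best is None or key < best:
                    best = key
                continue  # search stops at dated nodes
            queue.extend((c, d + 1) for c in topology.children[w])
        slope = best[0]
        age[v] = t_a - d_a * slope

    # monotonicity pass: clamp undated children below their parent
    eps = eps_rel * H
    n_clamped = 0
    for v in topology.preorder():
        v = int(v)
        p = int(topology.parent[v])
        if p < 0 or is_fixed[v] or not topology.children[v]:
            continue
        limit = age[p] - eps
        if age[v] > limit:
            age[v] = limit
            n_clamped += 1
    if n_clamped:
        logger.info("bladj_calibrate: clamped %d node age(s) to restore "
                    "parent>child ordering", n_clamped)

    age[topology.tips] = 0.0
    return Chronogram(topology.parent, age, topology.labels)


def make_polytomic_pseudochronogram(tree: Chronogram,
                                    collapse_spec: CollapseSpec,
                                    fix_fraction: float,
                                    seed: int | None = None,
                                    n_slices: int = 5,
                                    ) -> Chronogram:
    """Combined treatment: BLADJ pseudo-chronogram, then shallow collapse.

    The calibration nodes are drawn first (seeded stream 0), the
    pseudo-chronogram is built, and the collapse (seeded stream 1) excludes
    the calibrated nodes. With ``fix_fraction = 1`` and collapse fraction 0
    the result equals the input.
    """
    ss = np.random.SeedSequence(seed)
    rng_fix, rng_col = (np.random.default_rng(s) for s in ss.spawn(2))
    fixed = select_fixed_nodes(tree, fix_fraction, n_slices=n_slices,
                               rng=rng_fix)
    pseudo = bladj_calibrate(tree, fixed)
    spec = CollapseSpec(strategy="shallow", fraction=collapse_spec.fraction,
                        seed=collapse_spec.seed)
    return collapse_nodes(pseudo, spec, rng=rng_col,
                          protect=frozenset(fixed.ages))
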