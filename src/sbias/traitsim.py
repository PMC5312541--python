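"""Continuous-trait simulation with controlled phylogenetic signal.

Traits are drawn from the multivariate normal implied by Brownian motion on
the tree after Pagel-style lambda rescaling of the phylogenetic
variance-covariance (VCV) matrix: off-diagonal entries are multiplied by a
down-weighting coefficient lambda in [0, 1] while the diagonal is kept, so
lambda = 1 is pure Brownian motion and lambda = 0 destroys all covariance.
Sampling goes through the rescaled covariance directly (not branch-length
tree surgery); the two are distributionally identical for ultrametric trees
and the covariance route is exact for polytomies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .treespace import Chronogram

__all__ = ["TraitVector", "vcv", "lambda_rescale", "simulate_trait"]

logger = logging.getLogger(__name__)

#: eigenvalue floor used when Cholesky fails on a near-singular covariance
EIG_CLIP = 1e-12


@dataclass
class TraitVector:
    """Tip-indexed continuous trait plus the parameters that generated it."""
    values: np.ndarray
    tips: tuple[str, ...]
    lambda_sim: float
    sigma2: float = 1.0
    root_value: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.tips):
            raise ValueError("one value per tip required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trait values must be finite")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.tips), name="value")

    def reorder(self, tips: list[str]) -> np.ndarray:
        """Values aligned to another tip-label order (e.g. a degraded tree)."""
        pos = {t: i for i, t in enumerate(self.tips)}
        return self.values[[pos[t] for t in tips]]


def vcv(tree: Chronogram) -> np.ndarray:
    """Phylogenetic variance-covariance matrix, tips in ``tree.tip_labels`` order.

    ``C[i, j]`` is the shared root-to-tip path length of tips i and j, i.e.
    ``H - age(MRCA(i, j))``; the diagonal holds each tip's depth (``H`` for
    an ultrametric tree).
    """
    n = tree.n_tips
    row = {int(t): i for i, t in enumerate(tree.tips)}
    C = np.zeros((n, n))
    groups: dict[int, np.ndarray] = {}
    for v in tree.postorder():
        v = int(v)
        kids = tree.children[v]
        if not kids:
            groups[v] = np.array([row[v]], dtype=np.intp)
            continue
        sub = [groups.pop(c) for c in kids]
        cov = tree.height - tree.age[v]
        for a in range(len(sub)):
            for b in range(a + 1, len(sub)):
                C[np.ix_(sub[a], sub[b])] = cov
                C[np.ix_(sub[b], sub[a])] = cov
        groups[v] = np.concatenate(sub)
    idx = np.asarray([row[int(t)] for t in tree.tips], dtype=np.intp)
    C[idx, idx] = tree.height - tree.age[tree.tips]
    return C


def lambda_rescale(C: np.ndarray, lam: float) -> np.ndarray:
    """Multiply the off-diagonal entries of a VCV matrix by ``lam`` in [0, 1]."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    out = lam * C
    np.fill_diagonal(out, C.diagonal())
    return out


def _factor(S: np.ndarray) -> np.ndarray:
    """Lower-triangular-like factor L with L @ L.T = S (Cholesky, with
    eigenvalue clipping at ``EIG_CLIP`` as a fallback on near-singular input)."""
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        logger.warning("Cholesky failed; falling back to clipped "
                       "eigendecomposition")
        w, V = np.linalg.eigh(S)
        if np.min(w) < -1e-6 * np.max(np.abs(w)):
            raise
        return V * np.sqrt(np.clip(w, EIG_CLIP, None))


def simulate_trait(tree: Chronogram, lam: float, sigma2: float = 1.0,
                   a: float = 0.0, seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   C: np.ndarray | None = None) -> TraitVector:
    """Draw one trait vector from N(a*1, sigma2 * lambda_rescale(vcv, lam)).

    Parameters mirror the Brownian-motion simulation convention: root value
    ``a`` (trait units), instantaneous variance ``sigma2`` (trait units^2 per
    time unit) and signal coefficient ``lam``. Passing a precomputed ``C``
    (the tree's VCV) avoids recomputation across the lambda grid.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if C is None:
        C = vcv(tree)
    S = sigma2 * lambda_rescale(C, lam)
    L = _factor(S)
    values = a + L @ rng.standard_normal(C.shape[0])
    return TraitVector(values=values, tips=tuple(tree.tip_labels),
                       lambda_sim=lam, sigma2=sigma2, root_value=a, seed=seed)
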