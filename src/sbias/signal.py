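"""Blomberg's K and Pagel's lambda with their significance tests.

Both statistics are computed through the phylogenetic variance-covariance
matrix C, which makes them valid on binary *and* polytomic ultrametric trees
(no contrast resolution of polytomies needed). With the GLS ancestral mean
``a_hat = (1' C^-1 x) / (1' C^-1 1)``:

* **Blomberg's K** is the ratio ``(MSE0 / MSE) / E[MSE0 / MSE]`` with
  ``MSE0 = (x - a_hat 1)'(x - a_hat 1) / (n-1)``,
  ``MSE = (x - a_hat 1)' C^-1 (x - a_hat 1) / (n-1)`` and
  ``E[MSE0/MSE] = [tr(C) - n / (1' C^-1 1)] / (n-1)``. K = 1 matches the
  Brownian expectation. Significance comes from a randomization test that
  permutes trait values across tips and recomputes MSE — on a binary tree
  MSE equals the variance of standardized independent contrasts, so this is
  the classic observed-vs-randomized contrasts test; smaller MSE means more
  signal.

* **Pagel's lambda** multiplies the off-diagonal entries of C by lambda in
  [0, 1]; the profiled log-likelihood (ML variance, divisor n) is maximized
  over lambda and tested against lambda = 0 (complete phylogenetic
  independence) with a 1-df chi-square likelihood-ratio test.

For an ultrametric tree diag(C) = H, so ``C_lambda = lambda*C + (1-lambda)*H*I``
shares C's eigenvectors; one symmetric eigendecomposition per tree
(:class:`SignalEngine`) serves every lambda evaluation and every permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .traitsim import TraitVector, vcv
from .treespace import Chronogram

__all__ = [
    "SignalResult",
    "SignalEngine",
    "phylo_mean",
    "blomberg_k",
    "k_permutation_test",
    "lambda_loglik",
    "pagel_lambda_ml",
    "lambda_lrt",
    "signal_tests",
]

_LAM_GRID = np.linspace(0.0, 1.0, 21)
_BOUNDARY_TOL = 1e-6


class NumericalError(ArithmeticError):
    """Singular or non-positive-definite covariance encountered."""


@dataclass
class SignalResult:
    """K, its permutation p-value, and the lambda ML fit for one tree x trait."""
    K: float
    p_K: float
    lambda_hat: float
    lnL_hat: float
    lnL0: float
    p_lambda: float
    n_perm: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.lnL_hat < self.lnL0 - 1e-6:
            raise ValueError("lnL_hat below lnL0 beyond tolerance")
        for p in (self.p_K, self.p_lambda):
            if not (0.0 < p <= 1.0):
                raise ValueError(f"p-value {p} outside (0, 1]")


def _as_array(x, tree: Chronogram) -> np.ndarray:
    """Accept a TraitVector, pandas Series or plain array; align by tip label."""
    if isinstance(x, TraitVector):
        return x.reorder(tree.tip_labels)
    if hasattr(x, "reindex"):  # pandas Series
        v = x.reindex(tree.tip_labels).to_numpy(dtype=float)
        if np.any(np.isnan(v)):
            raise ValueError("trait series does not cover all tips")
        return v
    v = np.asarray(x, dtype=float)
    if v.shape[0] != tree.n_tips:
        raise ValueError("trait vector length does not match tip count")
    return v


class SignalEngine:
    """Per-tree spectral cache for K and lambda computations.

    Factorizes C once (symmetric eigendecomposition); all quadratic forms,
    the whole lambda profile likelihood, and every permutation replicate are
    then O(n) / O(n^2) operations in the eigenbasis.
    """

    def __init__(self, tree: Chronogram, C: np.ndarray | None = None):
        self.tree = tree
        if C is None:
            C = vcv(tree)
        self.C = C
        self.n = C.shape[0]
        diag = C.diagonal()
        self.H = float(diag.mean())
        if not np.allclose(diag, self.H, rtol=1e-6):
            raise NumericalError("SignalEngine requires an ultrametric tree "
                                 "(constant VCV diagonal)")
        w, V = np.linalg.eigh(C)
        if w.min() <= 0:
            raise NumericalError("VCV matrix is not positive definite")
        self.w = w
        self.V = V
        self.u = V.T @ np.ones(self.n)
        self.trC = float(diag.sum())
        # E[MSE0/MSE] under BM, from Blomberg et al.'s formula
        sum_inv = float(self.u @ (self.u / w))          # 1' C^-1 1
        self.k_expectation = (self.trC - self.n / sum_inv) / (self.n - 1)

    # -------------------------------------------------------------- #

    def project(self, x) -> np.ndarray:
        return self.V.T @ _as_array(x, self.tree)

    def _mse_pair(self, y: np.ndarray, lam: float = 1.0):
        """(MSE, MSE0) under C_lambda for projected trait(s) y (n,) or (n, B)."""
        e = lam * self.w + (1.0 - lam) * self.H
        wi = 1.0 / e
        uwi = self.u * wi
        a = (uwi @ y) / (uwi @ self.u)
        r = y - np.multiply.outer(self.u, a) if y.ndim == 2 else y - a * self.u
        mse = ((r * r).T @ wi).T / (self.n - 1)
        mse0 = (r * r).sum(axis=0) / (self.n - 1)
        return mse, mse0

    def blomberg_k(self, x) -> float:
        xv = _as_array(x, self.tree)
        if np.ptp(xv) == 0:
            raise ValueError("Blomberg's K is undefined for a constant trait")
        mse, mse0 = self._mse_pair(self.V.T @ xv)
        return float((mse0 / mse) / self.k_expectation)

    def k_permutation_test(self, x, n_perm: int = 999,
                           seed: int | None = None,
                           rng: np.random.Generator | None = None,
                           stat: str = "mse") -> float:
        """Randomization p-value for phylogenetic signal.

        ``stat="mse"`` (default) counts permutations with MSE <= observed
        (small contrast variance = strong signal); ``stat="k"`` counts
        permutations with K >= observed. p uses the add-one correction
        ``(1 + #extreme) / (1 + n_perm)`` and so is never 0.
        """
        if n_perm < 1:
            raise ValueError(f"n_perm must be >= 1, got {n_perm}")
        if stat not in ("mse", "k"):
            raise ValueError("stat must be 'mse' or 'k'")
        if rng is None:
            rng = np.random.default_rng(seed)
        xv = _as_array(x, self.tree)
        mse_obs, mse0_obs = self._mse_pair(self.V.T @ xv)
        perms = rng.permuted(
            np.broadcast_to(xv, (n_perm, self.n)).copy(), axis=1)
        mse_p, mse0_p = self._mse_pair(self.V.T @ perms.T)
        if stat == "mse":
            extreme = int(np.sum(mse_p <= mse_obs))
        else:
            extreme = int(np.sum(mse0_p / mse_p >= mse0_obs / mse_obs))
        return (1 + extreme) / (1 + n_perm)

    def lambda_loglik(self, x, lam: float) -> float:
        if not (0.0 <= lam <= 1.0):
            raise ValueError(f"lambda must be in [0, 1], got {lam}")
        return self._loglik(self.project(x), lam)

    def _loglik(self, y: np.ndarray, lam: float) -> float:
        e = lam * self.w + (1.0 - lam) * self.H
        if e.min() <= 0:
            return -np.inf
        wi = 1.0 / e
        uwi = self.u * wi
        a = float(uwi @ y) / float(uwi @ self.u)
        r = y - a * self.u
        sig2 = float((r * r) @ wi) / self.n
        if sig2 <= 0:
            return -np.inf
        return -0.5 * (self.n * np.log(2 * np.pi * sig2)
                       + float(np.log(e).sum()) + self.n)

    def pagel_lambda_ml(self, x=None, y_pre=None) -> tuple[float, float]:
        """Maximize the profiled lambda likelihood over [0, 1].

        A 21-point grid seeds a bounded Brent search (xatol 1e-6); boundary
        maxima are reported as exactly 0 or 1. Pass ``y_pre`` (an already
        projected trait) to skip the O(n^2) projection.
        """
        y = self.project(x) if y_pre is None else np.asarray(y_pre, dtype=float)
        grid_ll = np.array([self._loglik(y, g) for g in _LAM_GRID])
        i = int(np.argmax(grid_ll))
        lo = float(_LAM_GRID[max(i - 1, 0)])
        hi = float(_LAM_GRID[min(i + 1, len(_LAM_GRID) - 1)])
        best_lam, best_ll = float(_LAM_GRID[i]), float(grid_ll[i])
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda g: -self._loglik(y, g), bounds=(lo, hi),
                method="bounded", options={"xatol": 1e-6})
            if -res.fun > best_ll:
                best_lam, best_ll = float(res.x), float(-res.fun)
        if best_lam < _BOUNDARY_TOL:
            best_lam, best_ll = 0.0, self._loglik(y, 0.0)
        elif best_lam > 1.0 - _BOUNDARY_TOL:
            best_lam, best_ll = 1.0, self._loglik(y, 1.0)
        return best_lam, best_ll

    def lambda_lrt(self, x) -> float:
        """Likelihood-ratio p-value of lambda-hat against lambda = 0 (chi2, 1 df)."""
        y = self.project(x)
        _, lnl_hat = self.pagel_lambda_ml(y_pre=y)
        lnl0 = self._loglik(y, 0.0)
        D = max(0.0, 2.0 * (lnl_hat - lnl0))
        return float(stats.chi2.sf(D, df=1))

    def signal_tests(self, x, n_perm: int = 999, seed: int | None = None,
                     rng: np.random.Generator | None = None,
                     perm_stat: str = "mse",
                     metadata: dict | None = None) -> SignalResult:
        """Full battery: K + permutation test, lambda ML + LRT."""
        xv = _as_array(x, self.tree)
        y = self.V.T @ xv
        K = self.blomberg_k(xv)
        p_k = self.k_permutation_test(xv, n_perm=n_perm, seed=seed, rng=rng,
                                      stat=perm_stat)
        lam_hat, lnl_hat = self.pagel_lambda_ml(y_pre=y)
        lnl0 = self._loglik(y, 0.0)
        D = max(0.0, 2.0 * (lnl_hat - lnl0))
        p_lam = float(stats.chi2.sf(D, df=1))
        return SignalResult(K=K, p_K=p_k, lambda_hat=lam_hat, lnL_hat=lnl_hat,
                            lnL0=lnl0, p_lambda=p_lam, n_perm=n_perm,
                            metadata=metadata or {})


# ---------------------------------------------------------------------- #
# one-shot module-level functions


def phylo_mean(x, C: np.ndarray) -> float:
    """GLS ancestral mean ``(1' C^-1 x) / (1' C^-1 1)``."""
    xv = np.asarray(x.values if isinstance(x, TraitVector) else x, dtype=float)
    try:
        ci_x = np.linalg.solve(C, xv)
        ci_1 = np.linalg.solve(C, np.ones_like(xv))
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"singular VCV matrix: {exc}") from exc
    return float(ci_x.sum() / ci_1.sum())


def blomberg_k(x, tree: Chronogram) -> float:
    """Blomberg's K of a trait on a (possibly polytomic) ultrametric tree."""
    return SignalEngine(tree).blomberg_k(x)


def k_permutation_test(x, tree: Chronogram, n_perm: int = 999,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None,
                       stat: str = "mse") -> float:
    """Randomization p-value for K-type signal (see ``SignalEngine``)."""
    return SignalEngine(tree).k_permutation_test(x, n_perm=n_perm, seed=seed,
                                                 rng=rng, stat=stat)


def lambda_loglik(x, tree: Chronogram, lam: float) -> float:
    """Profiled log-likelihood of the lambda model at a given lambda."""
    return SignalEngine(tree).lambda_loglik(x, lam)


def pagel_lambda_ml(x, tree: Chronogram) -> tuple[float, float]:
    """(lambda_hat, lnL_hat): ML estimate of Pagel's lambda on [0, 1]."""
    return SignalEngine(tree).pagel_lambda_ml(x)


def lambda_lrt(x, tree: Chronogram) -> float:
    """Likelihood-ratio test p-value of lambda against lambda = 0."""
    return SignalEngine(tree).lambda_lrt(x)


def signal_tests(x, tree: Chronogram, n_perm: int = 999,
                 seed: int | None = None, perm_stat: str = "mse",
                 metadata: dict | None = None) -> SignalResult:
    """Run the full K + lambda battery on one tree x trait pair."""
    return SignalEngine(tree).signal_tests(x, n_perm=n_perm, seed=seed,
                                           perm_stat=perm_stat,
                                           metadata=metadata)
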