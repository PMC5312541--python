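"""Factorial bias study: paired true-vs-degraded significance tests.

The study design: simulate pure-birth chronograms, derive degraded versions
(polytomic chronograms by node collapsing, BLADJ-style pseudo-chronograms,
and their combination), simulate traits with graded phylogenetic signal on
the TRUE tree only, run both signal tests (Blomberg's K randomization test,
Pagel's lambda LRT) on the true tree and each degraded version with the
*same* trait vectors, and classify each pair of p-values with a dual-alpha
screen:

* type I bias  — no-signal null accepted on the true tree (p > 0.05) but
  rejected on the degraded tree (p < 0.01);
* type II bias — null rejected on the true tree (p < 0.01) but accepted on
  the degraded tree (p > 0.05).

The two alpha levels screen out marginal flips. Frequencies of each bias
type are tabulated per (index, treatment, tree size, degradation level,
simulated-lambda) cell, optionally stratified by tree shape (gamma deciles,
Colless deciles).

Seed discipline: one master seed per experiment; every stochastic component
draws from ``numpy.random.SeedSequence(master_seed, spawn_key=(stream, ...))``
with a documented stream layout, so any single replicate can be regenerated
in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import chi2

from . import __version__
from .degrade import (CollapseSpec, bladj_calibrate, collapse_nodes,
                      select_fixed_nodes)
from .signal import SignalEngine
from .traitsim import TraitVector, simulate_trait, vcv
from .treespace import (Chronogram, branch_length_sd, colless_index,
                        gamma_statistic, simulate_pure_birth, write_newick)

__all__ = [
    "ExperimentConfig",
    "classify_bias",
    "bias_frequencies",
    "stratify_by_shape",
    "run_pair_study",
    "run_experiment",
    "child_rng",
    "Treatment",
    "mean_k_brownian",
    "mean_lambda_recovery",
]

logger = logging.getLogger(__name__)

# seed-stream layout (spawn_key[0])
TREE_STREAM, TRAIT_STREAM, COLLAPSE_STREAM, FIX_STREAM, PERM_STREAM = range(5)

_STRATEGY_CODE = {"shallow": 0, "all": 1}


def child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Independent generator for one replicate: stream id + integer key."""
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------- #
# configuration


@dataclass
class ExperimentConfig:
    """Study conditions. Defaults are the desk-scale run; the full published
    design (sizes up to 1000 tips, 1000 trees per set) is supported by
    raising ``tree_sizes`` and ``n_trees``."""
    tree_sizes: tuple[int, ...] = (50, 100, 200)
    n_trees: int = 100
    birth_rate: float = 1.0
    lambda_grid: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10))
    collapse_fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    fix_fractions: tuple[float, ...] = (0.05, 0.15, 0.25, 0.35)
    n_slices: int = 5
    combined: bool = False          # shallow collapse on pseudo-chronograms
    sigma2: float = 1.0
    root_value: float = 0.0
    n_perm: int = 999
    alpha_accept: float = 0.05
    alpha_reject: float = 0.01
    master_seed: int = 0
    output_dir: str = "sbias_run"

    def __post_init__(self):
        if not self.alpha_reject < self.alpha_accept:
            raise ValueError("alpha_reject must be < alpha_accept")
        for f in (*self.collapse_fractions, *self.fix_fractions):
            if not (0.0 < f < 1.0):
                raise ValueError(f"fractions must be in (0, 1), got {f}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for k in ("tree_sizes", "lambda_grid", "collapse_fractions",
                  "fix_fractions"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------- #
# bias classification


def classify_bias(p_true: float, p_degraded: float,
                  alpha_accept: float = 0.05,
                  alpha_reject: float = 0.01) -> str:
    """Dual-alpha classification of one paired test: 'typeI', 'typeII' or 'none'."""
    for p in (p_true, p_degraded):
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value {p} outside (0, 1]")
    if p_true > alpha_accept and p_degraded < alpha_reject:
        return "typeI"
    if p_true < alpha_reject and p_degraded > alpha_accept:
        return "typeII"
    return "none"


def bias_frequencies(pairs: pd.DataFrame,
                     group_cols: tuple[str, ...] = ("index", "treatment",
                                                    "n_tips", "level",
                                                    "lambda_sim"),
                     alpha_accept: float = 0.05,
                     alpha_reject: float = 0.01) -> pd.DataFrame:
    """Per-cell type I / type II bias frequencies from paired p-values.

    ``pairs`` needs columns ``p_true`` and ``p_degraded`` plus the grouping
    keys. The denominator is all pairs in the cell. Cells that exist in the
    key product but received no pairs are emitted with ``n_pairs = 0`` and
    NaN frequencies rather than dropped.
    """
    cols = [c for c in group_cols if c in pairs.columns]
    df = pairs.copy()
    df["bias"] = [
        classify_bias(pt, pdg, alpha_accept, alpha_reject)
        for pt, pdg in zip(df["p_true"], df["p_degraded"])
    ]
    grouped = df.groupby(list(cols), sort=True)
    out = grouped.agg(
        n_pairs=("bias", "size"),
        freq_typeI=("bias", lambda b: np.mean(b == "typeI")),
        freq_typeII=("bias", lambda b: np.mean(b == "typeII")),
    )
    if cols:
        if len(cols) > 1:
            full = pd.MultiIndex.from_product(
                [sorted(df[c].unique()) for c in cols], names=cols)
        else:
            full = pd.Index(sorted(df[cols[0]].unique()), name=cols[0])
        out = out.reindex(full)
        out["n_pairs"] = out["n_pairs"].fillna(0).astype(int)
    return out.reset_index()


def stratify_by_shape(shape: pd.DataFrame, stat: str = "gamma",
                      lower_pct: float = 10.0, upper_pct: float = 90.0,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split trees into lower/upper shape-decile subsets per size category.

    ``shape`` needs columns ``n_tips``, ``tree`` and the statistic column
    (``gamma`` or ``colless``, computed on the true binary chronograms).
    Percentiles use linear interpolation; ties are inclusive (<= / >=).
    """
    if stat not in shape.columns:
        raise ValueError(f"column {stat!r} missing from shape table")
    lowers, uppers = [], []
    for _, sub in shape.groupby("n_tips"):
        lo = np.percentile(sub[stat], lower_pct)
        hi = np.percentile(sub[stat], upper_pct)
        lo_set = sub[sub[stat] <= lo]
        hi_set = sub[sub[stat] >= hi]
        for name, s in (("lower", lo_set), ("upper", hi_set)):
            if len(s) < 5:
                logger.warning("shape stratum %s/%s has only %d trees",
                               stat, name, len(s))
        lowers.append(lo_set)
        uppers.append(hi_set)
    return pd.concat(lowers), pd.concat(uppers)


# ---------------------------------------------------------------------- #
# treatments


@dataclass(frozen=True)
class Treatment:
    """One degradation condition applied to a true chronogram."""
    kind: str            # 'collapse_shallow' | 'collapse_all' | 'pseudo' | 'combined'
    level: float         # collapse fraction or fix fraction
    level2: float = 0.0  # collapse fraction of the combined treatment

    @property
    def name(self) -> str:
        if self.kind == "combined":
            return f"combined_f{self.level:g}_c{self.level2:g}"
        return f"{self.kind}_{self.level:g}"


def apply_treatment(tree: Chronogram, trt: Treatment, master_seed: int,
                    size: int, rep: int, n_slices: int = 5) -> Chronogram:
    """Build one degraded tree; seeds derive only from (treatment, size, rep)."""
    code = {"collapse_shallow": 0, "collapse_all": 1,
            "pseudo": 2, "combined": 3}[trt.kind]
    lvl_key = int(round(trt.level * 100))
    if trt.kind in ("collapse_shallow", "collapse_all"):
        strategy = "shallow" if trt.kind == "collapse_shallow" else "all"
        rng = child_rng(master_seed, COLLAPSE_STREAM, size, rep, code, lvl_key)
        return collapse_nodes(tree, CollapseSpec(strategy, trt.level), rng=rng)
    if trt.kind == "pseudo":
        rng = child_rng(master_seed, FIX_STREAM, size, rep, code, lvl_key)
        fixed = select_fixed_nodes(tree, trt.level, n_slices=n_slices, rng=rng)
        return bladj_calibrate(tree, fixed)
    if trt.kind == "combined":
        rng_fix = child_rng(master_seed, FIX_STREAM, size, rep, code, lvl_key)
        fixed = select_fixed_nodes(tree, trt.level, n_slices=n_slices,
                                   rng=rng_fix)
        pseudo = bladj_calibrate(tree, fixed)
        rng_col = child_rng(master_seed, COLLAPSE_STREAM, size, rep, code,
                            lvl_key, int(round(trt.level2 * 100)))
        return collapse_nodes(pseudo, CollapseSpec("shallow", trt.level2),
                              rng=rng_col, protect=frozenset(fixed.ages))
    raise ValueError(f"unknown treatment kind {trt.kind!r}")


def _check_degraded(true: Chronogram, deg: Chronogram) -> None:
    """Degradations must preserve tips, labels, height and ultrametricity."""
    if sorted(deg.tip_labels) != sorted(true.tip_labels):
        raise AssertionError("degradation changed the tip set")
    if abs(deg.height - true.height) > 1e-8 * true.height:
        raise AssertionError("degradation changed the tree height")


# ---------------------------------------------------------------------- #
# paired studies


def run_pair_study(sizes, n_trees: int, treatments, master_seed: int,
                   lambda_grid=None, indices: tuple[str, ...] = ("lambda",),
                   n_perm: int = 999, birth_rate: float = 1.0,
                   sigma2: float = 1.0, root_value: float = 0.0,
                   n_slices: int = 5,
                   collect_estimates: bool = False) -> pd.DataFrame:
    """Paired true-vs-degraded p-values for the requested signal indices.

    Returns a long DataFrame with one row per
    (index, treatment, size, tree, lambda_sim) containing ``p_true`` and
    ``p_degraded`` (plus the point estimates when ``collect_estimates``).
    Traits are always simulated on the TRUE tree and reused, unchanged, on
    every degraded counterpart of that tree.
    """
    if lambda_grid is None:
        lambda_grid = tuple(round(0.1 * i, 1) for i in range(1, 10))
    treatments = list(treatments)
    rows = []
    for size in sizes:
        for rep in range(n_trees):
            tree = simulate_pure_birth(
                size, birth_rate,
                rng=child_rng(master_seed, TREE_STREAM, size, rep))
            C_true = vcv(tree)
            eng_true = SignalEngine(tree, C=C_true)
            variants = []
            for trt in treatments:
                deg = apply_treatment(tree, trt, master_seed, size, rep,
                                      n_slices=n_slices)
                _check_degraded(tree, deg)
                variants.append((trt, SignalEngine(deg)))
            for li, lam in enumerate(lambda_grid):
                x = simulate_trait(
                    tree, lam, sigma2=sigma2, a=root_value,
                    rng=child_rng(master_seed, TRAIT_STREAM, size, rep, li),
                    C=C_true)
                engines = [("true", eng_true)] + [
                    (trt.name, eng) for trt, eng in variants]
                p_vals: dict[tuple[str, str], float] = {}
                est: dict[tuple[str, str], float] = {}
                for vi, (vname, eng) in enumerate(engines):
                    xv = x.reorder(eng.tree.tip_labels)
                    y = eng.V.T @ xv
                    if "lambda" in indices:
                        lam_hat, lnl_hat = eng.pagel_lambda_ml(y_pre=y)
                        lnl0 = eng._loglik(y, 0.0)
                        D = max(0.0, 2.0 * (lnl_hat - lnl0))
                        p_vals[("lambda", vname)] = float(chi2.sf(D, 1))
                        est[("lambda", vname)] = lam_hat
                    if "K" in indices:
                        rng_p = child_rng(master_seed, PERM_STREAM, size, rep,
                                          li, vi)
                        p_vals[("K", vname)] = eng.k_permutation_test(
                            xv, n_perm=n_perm, rng=rng_p)
                        est[("K", vname)] = eng.blomberg_k(xv)
                for idx in indices:
                    for trt, _eng in variants:
                        row = dict(index=idx, treatment=trt.name,
                                   kind=trt.kind, level=trt.level,
                                   n_tips=size, tree=rep, lambda_sim=lam,
                                   p_true=p_vals[(idx, "true")],
                                   p_degraded=p_vals[(idx, trt.name)])
                        if collect_estimates:
                            row["est_true"] = est[(idx, "true")]
                            row["est_degraded"] = est[(idx, trt.name)]
                        rows.append(row)
    return pd.DataFrame(rows)


def mean_k_brownian(n_trees: int, n_tips: int, master_seed: int,
                    birth_rate: float = 1.0) -> float:
    """Mean Blomberg's K over replicate pure-BM traits on true chronograms."""
    ks = []
    for rep in range(n_trees):
        tree = simulate_pure_birth(
            n_tips, birth_rate,
            rng=child_rng(master_seed, TREE_STREAM, n_tips, rep))
        C = vcv(tree)
        x = simulate_trait(tree, 1.0,
                           rng=child_rng(master_seed, TRAIT_STREAM, n_tips,
                                         rep, 0),
                           C=C)
        ks.append(SignalEngine(tree, C=C).blomberg_k(x.values))
    return float(np.mean(ks))


def mean_lambda_recovery(n_trees: int, n_tips: int, lam_sim: float,
                         master_seed: int, birth_rate: float = 1.0) -> float:
    """Mean ML estimate of Pagel's lambda for traits simulated at ``lam_sim``."""
    lams = []
    for rep in range(n_trees):
        tree = simulate_pure_birth(
            n_tips, birth_rate,
            rng=child_rng(master_seed, TREE_STREAM, n_tips, rep))
        C = vcv(tree)
        x = simulate_trait(tree, lam_sim,
                           rng=child_rng(master_seed, TRAIT_STREAM, n_tips,
                                         rep, 0),
                           C=C)
        lam_hat, _ = SignalEngine(tree, C=C).pagel_lambda_ml(x.values)
        lams.append(lam_hat)
    return float(np.mean(lams))


# ---------------------------------------------------------------------- #
# full pipeline


def run_experiment(config: ExperimentConfig) -> Path:
    """Run the full factorial study and write all tables.

    Output directory receives ``trees/*.nwk``, ``traits.tsv``,
    ``results.tsv`` (per tree x treatment x trait signal results),
    ``bias_table.tsv``, shape-stratified bias tables and ``manifest.yaml``.
    The run is resumable per tree: completed per-tree result chunks under
    ``chunks/`` are not recomputed.
    """
    out = Path(config.output_dir)
    (out / "trees").mkdir(parents=True, exist_ok=True)
    (out / "chunks").mkdir(exist_ok=True)

    treatments = (
        [Treatment("collapse_shallow", f) for f in config.collapse_fractions]
        + [Treatment("collapse_all", f) for f in config.collapse_fractions]
        + [Treatment("pseudo", f) for f in config.fix_fractions]
    )
    if config.combined:
        treatments += [Treatment("combined", ff, cf)
                       for ff in config.fix_fractions
                       for cf in config.collapse_fractions]

    shape_rows, trait_rows, failures = [], [], []
    for size in config.tree_sizes:
        for rep in range(config.n_trees):
            chunk = out / "chunks" / f"n{size}_r{rep}.tsv"
            tree_path = out / "trees" / f"n{size}_r{rep}.nwk"
            try:
                tree = simulate_pure_birth(
                    size, config.birth_rate,
                    rng=child_rng(config.master_seed, TREE_STREAM, size, rep))
                shape_rows.append(dict(
                    n_tips=size, tree=rep,
                    gamma=gamma_statistic(tree),
                    colless=colless_index(tree),
                    branch_length_sd=branch_length_sd(tree)))
                tree_path.write_text(write_newick(tree) + "\n")
                if chunk.exists():
                    continue
                res = _run_one_tree(tree, size, rep, treatments, config,
                                    trait_rows)
                res.to_csv(chunk, sep="\t", index=False)
            except Exception as exc:  # noqa: BLE001 - logged & counted
                logger.exception("tree n=%d rep=%d failed", size, rep)
                failures.append(dict(n_tips=size, tree=rep, error=str(exc)))
            else:
                logger.info("completed tree n=%d rep=%d", size, rep)

    results = pd.concat(
        [pd.read_csv(out / "chunks" / f"n{s}_r{r}.tsv", sep="\t")
         for s in config.tree_sizes for r in range(config.n_trees)
         if (out / "chunks" / f"n{s}_r{r}.tsv").exists()],
        ignore_index=True)
    results.to_csv(out / "results.tsv", sep="\t", index=False)
    shape = pd.DataFrame(shape_rows)
    shape.to_csv(out / "shape_stats.tsv", sep="\t", index=False)
    if trait_rows:
        pd.DataFrame(trait_rows).to_csv(out / "traits.tsv", sep="\t",
                                        index=False)

    pairs = _paired_table(results)
    bias_frequencies(
        pairs, alpha_accept=config.alpha_accept,
        alpha_reject=config.alpha_reject,
    ).to_csv(out / "bias_table.tsv", sep="\t", index=False)
    for stat in ("gamma", "colless"):
        lo, hi = stratify_by_shape(shape, stat)
        for name, subset in (("low", lo), ("high", hi)):
            keys = set(zip(subset["n_tips"], subset["tree"]))
            mask = [
                (n, t) in keys
                for n, t in zip(pairs["n_tips"], pairs["tree"])]
            bias_frequencies(
                pairs[np.asarray(mask)],
                alpha_accept=config.alpha_accept,
                alpha_reject=config.alpha_reject,
            ).to_csv(out / f"bias_table_{stat}_{name}.tsv", sep="\t",
                     index=False)

    manifest = dict(config=asdict(config), version=__version__,
                    numpy=np.__version__, pandas=pd.__version__,
                    n_failures=len(failures), failures=failures)
    for k, v in manifest["config"].items():
        if isinstance(v, tuple):
            manifest["config"][k] = list(v)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out


def _run_one_tree(tree: Chronogram, size: int, rep: int, treatments,
                  config: ExperimentConfig, trait_rows: list) -> pd.DataFrame:
    C_true = vcv(tree)
    engines = [("true", SignalEngine(tree, C=C_true))]
    for trt in treatments:
        deg = apply_treatment(tree, trt, config.master_seed, size, rep,
                              n_slices=config.n_slices)
        _check_degraded(tree, deg)
        engines.append((trt.name, SignalEngine(deg)))
    rows = []
    for li, lam in enumerate(config.lambda_grid):
        x = simulate_trait(
            tree, lam, sigma2=config.sigma2, a=config.root_value,
            rng=child_rng(config.master_seed, TRAIT_STREAM, size, rep, li),
            C=C_true)
        checksum = float(np.sum(x.values))
        for tip, val in zip(x.tips, x.values):
            trait_rows.append(dict(n_tips=size, tree=rep, lambda_sim=lam,
                                   tip=tip, value=val))
        for vi, (vname, eng) in enumerate(engines):
            rng_p = child_rng(config.master_seed, PERM_STREAM, size, rep,
                              li, vi)
            res = eng.signal_tests(x, n_perm=config.n_perm, rng=rng_p)
            rows.append(dict(
                n_tips=size, tree=rep, treatment=vname, lambda_sim=lam,
                K=res.K, p_K=res.p_K, lambda_hat=res.lambda_hat,
                lnL_hat=res.lnL_hat, lnL0=res.lnL0, p_lambda=res.p_lambda,
                n_perm=res.n_perm, trait_checksum=checksum))
    return pd.DataFrame(rows)


def _paired_table(results: pd.DataFrame) -> pd.DataFrame:
    """Join degraded rows to their true-chronogram row; melt K and lambda."""
    true = results[results["treatment"] == "true"]
    deg = results[results["treatment"] != "true"]
    keys = ["n_tips", "tree", "lambda_sim"]
    merged = deg.merge(true[keys + ["p_K", "p_lambda", "trait_checksum"]],
                       on=keys, suffixes=("", "_true"), validate="m:1")
    if not np.allclose(merged["trait_checksum"],
                       merged["trait_checksum_true"]):
        raise AssertionError("pairing integrity violated: trait checksums "
                             "differ between true and degraded rows")
    parts = []
    for idx, col in (("K", "p_K"), ("lambda", "p_lambda")):
        part = merged[keys + ["treatment"]].copy()
        part["index"] = idx
        part["p_true"] = merged[f"{col}_true"].to_numpy()
        part["p_degraded"] = merged[col].to_numpy()
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    out["level"] = [t.rsplit("_", 1)[-1] for t in out["treatment"]]
    return out
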