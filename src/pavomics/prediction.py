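"""Multi-kernel GBLUP genomic prediction.

Any omic layer (array SNPs, sequence variants, ePAV calls, expression
levels) enters as an inbred x feature matrix W whose columns are centered
and standardized; its additive relationship matrix is the VanRaden
cross-product G = W W' / m.  Kernels are combined as a weighted sum with
weights on the unit simplex (grid-searched in 0.1 increments), and genetic
values are predicted with GBLUP: y = 1 mu + g + e, g ~ N(0, sigma_g^2 G),
e ~ N(0, sigma_e^2 I), variance components by REML over the single ratio
lambda = sigma_e^2 / sigma_g^2 using one eigendecomposition of the training
kernel per fit.  Accuracy is the Pearson correlation r(g_hat, y) in
five-fold cross-validation; the read-downsampling experiment thins raw
counts binomially and re-runs the whole feature-extraction pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import pav_calling as pc
from .variants import filter_variants
from .synthetic import ExpressionTensor

__all__ = [
    "FeatureMatrix",
    "KernelSet",
    "CVResult",
    "preprocess_features",
    "vanraden_kernel",
    "simplex_grid",
    "combine_kernels",
    "gblup_fit",
    "fold_plan",
    "cross_validate",
    "grid_search",
    "downsample_experiment",
    "epav_feature_matrix",
]

PSD_TOL = 1e-8


@dataclass
class FeatureMatrix:
    """Preprocessed inbred x feature matrix: columns centered, unit
    variance, zero-variance columns dropped (count kept)."""

    W: pd.DataFrame
    label: str = ""
    n_dropped: int = 0

    @property
    def m(self) -> int:
        return self.W.shape[1]


@dataclass
class KernelSet:
    """Named relationship matrices with combination weights on the simplex."""

    kernels: dict[str, pd.DataFrame]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.kernels):
            raise ValueError("one weight per kernel required")
        if (self.weights < -1e-12).any() or abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be non-negative and sum to 1")
        for name, G in self.kernels.items():
            arr = G.to_numpy()
            if not np.allclose(arr, arr.T, atol=1e-10):
                raise ValueError(f"kernel {name}: not symmetric")
            if np.linalg.eigvalsh(arr).min() < -PSD_TOL * max(1.0, abs(arr).max()):
                raise ValueError(f"kernel {name}: not positive semi-definite")


@dataclass
class CVResult:
    """Cross-validation accuracies (length folds x reps, NaN for folds with
    undefined correlation) and their median."""

    accuracies: np.ndarray
    label: str = ""
    seed: int = 0
    n_na: int = 0

    @property
    def median(self) -> float:
        return float(np.nanmedian(self.accuracies))


def preprocess_features(W: pd.DataFrame, label: str = "") -> FeatureMatrix:
    """Center and standardize columns to unit variance; zero-variance
    columns are dropped and counted."""
    # contiguous copy: results must not depend on the frame's memory layout
    X = np.ascontiguousarray(W.to_numpy(dtype=float))
    sd = X.std(axis=0)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return FeatureMatrix(
        pd.DataFrame(X, index=W.index, columns=W.columns[keep]),
        label=label,
        n_dropped=int((~keep).sum()),
    )


def vanraden_kernel(fm: FeatureMatrix | pd.DataFrame, label: str = "") -> pd.DataFrame:
    """Additive relationship matrix G = W W' / m from standardized columns
    (diagonal mean ~ 1)."""
    if isinstance(fm, pd.DataFrame):
        fm = preprocess_features(fm, label)
    if fm.m == 0:
        raise ValueError("no informative features left after preprocessing")
    X = fm.W.to_numpy()
    G = X @ X.T / fm.m
    return pd.DataFrame(G, index=fm.W.index, columns=fm.W.index)


def simplex_grid(k: int, step: float = 0.1) -> list[tuple[float, ...]]:
    """All non-negative k-vectors with entries a multiple of ``step``
    summing to 1; their number is C(1/step + k - 1, k - 1)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = 1.0 / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"1/step must be an integer, got step={step}")
    n = int(round(n))

    def comps(total: int, parts: int):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in comps(total - first, parts - 1):
                yield (first, *rest)

    return [tuple(c / n for c in comp) for comp in comps(n, k)]


def combine_kernels(ks: KernelSet) -> pd.DataFrame:
    """Joined weighted relationship matrix sum_i w_i G_i."""
    names = list(ks.kernels)
    idx = ks.kernels[names[0]].index
    out = np.zeros((len(idx), len(idx)))
    for w, name in zip(ks.weights, names):
        G = ks.kernels[name]
        if not G.index.equals(idx):
            raise ValueError("kernels must cover identical inbreds in order")
        out += w * G.to_numpy()
    return pd.DataFrame(out, index=idx, columns=idx)


# ---------------------------------------------------------------------------
# GBLUP with 1-D REML
# ---------------------------------------------------------------------------


def _reml_lambda(y: np.ndarray, K: np.ndarray, bounds=(-8.0, 8.0)) -> float:
    """REML estimate of lambda = sigma_e^2 / sigma_g^2 by profiling the
    restricted likelihood over log lambda, using the eigendecomposition of
    the projected kernel (intercept-only fixed effects)."""
    n = len(y)
    P = np.eye(n) - np.ones((n, n)) / n
    theta, U = np.linalg.eigh(P @ K @ P)
    # intercept projection removes one dimension
    keep = np.argsort(theta)[1:]
    theta = theta[keep]
    eta2 = (U[:, keep].T @ y) ** 2

    def neg_restricted_ll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        denom = theta + lam
        sg2 = float(np.sum(eta2 / denom) / (n - 1))
        if sg2 <= 0:
            return np.inf
        return 0.5 * ((n - 1) * np.log(sg2) + np.sum(np.log(denom)))

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=bounds, method="bounded")
    return float(np.exp(res.x))


def gblup_fit(
    y_train: np.ndarray,
    G: pd.DataFrame,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    lam: float | None = None,
) -> tuple[np.ndarray, float, float]:
    """Fit GBLUP on the training inbreds and predict the validation ones.

    Returns (predictions for val_idx, mu_hat, lambda_hat).  ``lam`` fixes
    the variance ratio instead of estimating it by REML.
    """
    if len(train_idx) < 3:
        raise ValueError("need at least 3 training inbreds")
    y = np.asarray(y_train, dtype=float)
    Gm = G.to_numpy()
    Ktt = Gm[np.ix_(train_idx, train_idx)]
    Kvt = Gm[np.ix_(val_idx, train_idx)]
    if lam is None:
        lam = _reml_lambda(y, Ktt)
    A = Ktt + lam * np.eye(len(train_idx))
    try:
        Ainv_y = np.linalg.solve(A, y)
        Ainv_1 = np.linalg.solve(A, np.ones(len(y)))
    except np.linalg.LinAlgError:
        A = A + 1e-8 * np.eye(len(train_idx))
        Ainv_y = np.linalg.solve(A, y)
        Ainv_1 = np.linalg.solve(A, np.ones(len(y)))
    mu = float(Ainv_y.sum() / Ainv_1.sum())
    alpha = np.linalg.solve(A, y - mu)
    return mu + Kvt @ alpha, mu, float(lam)


def fold_plan(n: int, folds: int, reps: int, seed: int) -> list[np.ndarray]:
    """Per replicate, a random assignment of the n inbreds to ``folds``
    disjoint subsets with sizes differing by at most one (e.g. 5/5/5/4/4
    for n = 23)."""
    if n < folds:
        raise ValueError("need at least as many inbreds as folds")
    rng = np.random.default_rng(seed)
    plans = []
    for _ in range(reps):
        perm = rng.permutation(n)
        assign = np.empty(n, dtype=int)
        for f, chunk in enumerate(np.array_split(perm, folds)):
            assign[chunk] = f
        plans.append(assign)
    return plans


def cross_validate(
    y: pd.Series,
    G: pd.DataFrame,
    folds: int = 5,
    reps: int = 200,
    seed: int = 0,
    plan: list[np.ndarray] | None = None,
    label: str = "",
) -> CVResult:
    """k-fold cross-validated prediction accuracy, replicated.

    Per run the accuracy is the Pearson correlation between GBLUP
    predictions and observed entry means of the left-out subset; runs with
    undefined correlation (zero variance on either side) are recorded as
    NaN and excluded from the median.
    """
    if not y.index.equals(G.index):
        raise ValueError("phenotype and kernel must cover identical inbreds in order")
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    if plan is None:
        plan = fold_plan(n, folds, reps, seed)
    acc = np.empty(len(plan) * folds)
    k = 0
    n_na = 0
    for assign in plan:
        for f in range(folds):
            val = np.where(assign == f)[0]
            train = np.where(assign != f)[0]
            pred, _, _ = gblup_fit(yv[train], G, train, val)
            if np.std(yv[val]) == 0 or np.std(pred) == 0:
                acc[k] = np.nan
                n_na += 1
            else:
                acc[k] = stats.pearsonr(pred, yv[val])[0]
            k += 1
    return CVResult(acc, label=label, seed=seed, n_na=n_na)


def grid_search(
    y: pd.Series,
    kernels: dict[str, pd.DataFrame],
    folds: int = 5,
    reps: int = 200,
    seed: int = 0,
    step: float = 0.1,
) -> tuple[pd.DataFrame, tuple[float, ...]]:
    """Median accuracy at every simplex grid point, with a fold plan shared
    across weight settings so comparisons are paired.

    Returns (table with one row per weight vector, argmax weights).
    """
    if len(kernels) < 2:
        raise ValueError("grid search needs at least 2 kernels")
    names = list(kernels)
    grid = simplex_grid(len(names), step)
    plan = fold_plan(len(y), folds, reps, seed)
    rows = []
    for w in grid:
        joint = combine_kernels(KernelSet(kernels, np.array(w)))
        res = cross_validate(y, joint, folds, reps, seed, plan=plan)
        rows.append((*w, res.median))
    table = pd.DataFrame(rows, columns=[*names, "median_accuracy"])
    best = table["median_accuracy"].idxmax()
    return table, tuple(table.loc[best, names])


# ---------------------------------------------------------------------------
# read downsampling
# ---------------------------------------------------------------------------


def epav_feature_matrix(consensus: pc.PACallMatrix, genes: set) -> pd.DataFrame:
    """ePAV genes coded present=1/absent=0 (no-calls mean-imputed) as an
    inbred x gene feature matrix."""
    from .variants import epav_vector_matrix

    return epav_vector_matrix(consensus, sorted(genes)).T


def _thin_coverage(
    expr: ExpressionTensor, tissue: str, fraction: float, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[np.ndarray], pd.Series]:
    """Binomially thin each coverage bin of one tissue; recompute library
    sizes and FPKM from the thinned counts."""
    cov = expr.coverage[tissue]
    thinned = [rng.binomial(prof, fraction) for prof in cov]
    counts = np.vstack([prof.sum(axis=1) for prof in thinned]).astype(float)
    lib = counts.sum(axis=0)
    lengths = expr.gene_lengths.to_numpy()[:, None] / 1e3
    with np.errstate(invalid="ignore", divide="ignore"):
        fpkm = counts / lengths / (lib[None, :] / 1e6)
    fpkm = np.nan_to_num(fpkm)
    cols = expr.inbreds(tissue)
    return (
        pd.DataFrame(fpkm, index=expr.genes, columns=cols),
        thinned,
        pd.Series(lib, index=cols),
    )


def _thin_variants(
    raw: pd.DataFrame, fraction: float, rng: np.random.Generator
) -> pd.DataFrame:
    out = raw.copy()
    out["depth"] = rng.binomial(raw["depth"].to_numpy(), fraction)
    out.loc[out["depth"] == 0, "allele"] = ""
    return out


def downsample_experiment(
    expr: ExpressionTensor,
    raw_variants: pd.DataFrame,
    y: pd.Series,
    fractions: tuple[float, ...] = (0.10, 0.05, 0.01, 0.005),
    n_reps: int = 30,
    seed: int = 0,
    tissue: str = "seedling",
    t: int = 2,
    folds: int = 5,
    cv_reps: int = 20,
    grid_step: float = 0.5,
) -> pd.DataFrame:
    """Prediction accuracy as a function of sequencing depth.

    Per replicate and fraction, reads (coverage bins) of the chosen tissue
    and the variant depth fields are thinned binomially; expression, ePAV
    calls and the variant matrix are recomputed from the thinned data, and
    single-kernel plus best-grid-combination accuracies are cross-validated.
    Fraction 1.0 reproduces the full pipeline exactly.
    """
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError(f"fractions must lie in (0, 1], got {f}")
    if expr.coverage is None:
        raise ValueError("coverage profiles are required for downsampling")
    seedq = np.random.SeedSequence(seed)
    plan = fold_plan(len(y), folds, cv_reps, seed)
    tissue_raw = raw_variants[raw_variants["tissue"] == tissue] if "tissue" in raw_variants else raw_variants
    rows = []
    for rep, child in enumerate(seedq.spawn(n_reps)):
        rng = np.random.default_rng(child)
        for f in fractions:
            fpkm, _, lib = _thin_coverage(expr, tissue, f, rng)
            consensus = pc.merge_tissues([pc.call_tissue_pav(fpkm, tissue)])
            epav = pc.designate_epav(consensus, t)
            vm = filter_variants(_thin_variants(tissue_raw, f, rng))

            kernels: dict[str, pd.DataFrame] = {}
            n_feat: dict[str, int] = {}
            fm_t = preprocess_features(fpkm.T.loc[y.index], "T")
            if fm_t.m:
                kernels["T"] = vanraden_kernel(fm_t)
            n_feat["T"] = fm_t.m
            if epav.genes:
                fm_e = preprocess_features(epav_feature_matrix(consensus, epav.genes).loc[y.index], "ePAV")
                if fm_e.m:
                    kernels["ePAV"] = vanraden_kernel(fm_e)
                n_feat["ePAV"] = fm_e.m
            else:
                n_feat["ePAV"] = 0
            if len(vm.alleles):
                sv_W = vm.alleles.T.reindex(y.index)
                fm_s = preprocess_features(sv_W, "SV")
                if fm_s.m:
                    kernels["SV"] = vanraden_kernel(fm_s)
                n_feat["SV"] = fm_s.m
            else:
                n_feat["SV"] = 0

            for name, G in kernels.items():
                res = cross_validate(y, G, folds, cv_reps, seed, plan=plan, label=name)
                rows.append((f, rep, name, res.median, n_feat[name], float(lib.sum())))
            if len(kernels) >= 2:
                table, best = grid_search(
                    y, kernels, folds, cv_reps, seed, step=grid_step
                )
                rows.append(
                    (
                        f,
                        rep,
                        "optimal_combination",
                        float(table["median_accuracy"].max()),
                        sum(n_feat.values()),
                        float(lib.sum()),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["fraction", "replicate", "predictor", "median_accuracy", "n_features", "thinned_reads"],
    )
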