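"""Population-structure and distributional statistics.

Covers the descriptive comparisons between the molecular layers: PCA
concordance between two feature matrices over the same inbreds, Mantel
tests between Euclidean distance matrices, a permutation test of whether
ePAV genes are uniformly spread along chromosomes (sliding-window
proportions), and the ePAV vs non-ePAV gene-length comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix as _SkbioDM
from skbio.stats.distance import mantel as _skbio_mantel

__all__ = [
    "DistanceMatrix",
    "distance_matrix",
    "pca_concordance",
    "mantel_test",
    "epav_distribution_test",
    "length_comparison",
]


@dataclass
class DistanceMatrix:
    """Inbred x inbred Euclidean distances from one feature matrix."""

    distances: pd.DataFrame
    source: str

    def __post_init__(self) -> None:
        d = self.distances.to_numpy()
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0) or (d < 0).any():
            raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")


def distance_matrix(features: pd.DataFrame, source: str = "") -> DistanceMatrix:
    """Euclidean distances between inbreds (rows of ``features``)."""
    d = squareform(pdist(features.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(pd.DataFrame(d, index=features.index, columns=features.index), source)


def _standardize(W: pd.DataFrame) -> np.ndarray:
    X = W.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    return X[:, sd > 0] / sd[sd > 0]


def _pc_scores(W: pd.DataFrame, n_components: int) -> np.ndarray:
    X = _standardize(W)
    # PCA via SVD of the centered/standardized matrix; scores = U * s
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :n_components] * s[:n_components]


def pca_concordance(
    W1: pd.DataFrame, W2: pd.DataFrame, n_components: int = 2
) -> pd.DataFrame:
    """Squared correlation between paired principal-component scores of two
    feature matrices over the same inbreds.

    Components are sign-aligned (r >= 0 reported via r^2, which is sign
    invariant); returns one row per component with r2 and the two-sided
    correlation p-value.
    """
    if not W1.index.equals(W2.index):
        raise ValueError("feature matrices must cover identical inbreds in order")
    if len(W1) < 3:
        raise ValueError("need at least 3 inbreds for PCA")
    S1 = _pc_scores(W1, n_components)
    S2 = _pc_scores(W2, n_components)
    rows = []
    for k in range(n_components):
        r, p = stats.pearsonr(S1[:, k], S2[:, k])
        rows.append((k + 1, r * r, p))
    return pd.DataFrame(rows, columns=["component", "r2", "p_value"]).set_index("component")


def mantel_test(
    d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of the off-diagonal distances, with
    a permutation p-value from ``n_perm`` row/column permutations
    ((b + 1) / (m + 1) estimator, never exactly zero)."""
    if list(d1.distances.index) != list(d2.distances.index):
        raise ValueError("distance matrices must cover identical inbreds")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    ids = [str(i) for i in d1.distances.index]
    r, p, _ = _skbio_mantel(
        _SkbioDM(d1.distances.to_numpy(), ids=ids),
        _SkbioDM(d2.distances.to_numpy(), ids=ids),
        method="pearson",
        permutations=n_perm,
        seed=seed,
    )
    return float(r), float(p)


def _window_membership(
    positions: np.ndarray, lo: int, hi: int, window: int, step: int
) -> np.ndarray:
    """Boolean windows x genes membership matrix for sliding windows."""
    starts = np.arange(lo, max(hi - window, lo) + 1, step)
    if len(starts) == 0:
        starts = np.array([lo])
    M = (positions[None, :] >= starts[:, None]) & (
        positions[None, :] < starts[:, None] + window
    )
    return M


def epav_distribution_test(
    epav_genes: set,
    annotation: pd.DataFrame,
    window: int = 20_000_000,
    n_perm: int = 999,
    seed: int = 0,
    step: int | None = None,
    statistic: str = "range",
) -> pd.DataFrame:
    """Permutation test of uniform ePAV placement along each chromosome.

    Genes are binned into sliding windows (default step = window / 2); the
    observed per-window ePAV proportion is summarised per chromosome by the
    range (max - min) of proportions (or a chi-square statistic), and
    compared with the same statistic under random permutation of the ePAV
    labels over all genes.  Chromosomes spanning fewer than two windows are
    skipped with a warning flag in the output.
    """
    if statistic not in ("range", "chi2"):
        raise ValueError(f"unknown statistic {statistic!r}")
    step = step or window // 2
    rng = np.random.default_rng(seed)
    labels = annotation.index.isin(list(epav_genes)).astype(float)
    mid = ((annotation["start"] + annotation["end"]) // 2).to_numpy()
    chroms = annotation["chrom"].to_numpy()

    perms = np.stack([rng.permutation(labels) for _ in range(n_perm)])
    rows = []
    for c in pd.unique(chroms):
        on = chroms == c
        pos = mid[on]
        M = _window_membership(pos, int(pos.min()), int(pos.max()) + 1, window, step)
        counts = M.sum(axis=1)
        ok = counts > 0
        M, counts = M[ok], counts[ok]
        if M.shape[0] < 2:
            rows.append((c, np.nan, np.nan, M.shape[0], True))
            continue

        def stat(lab: np.ndarray) -> np.ndarray:
            props = (M @ lab.T) / counts[:, None]  # windows x draws
            if statistic == "range":
                return props.max(axis=0) - props.min(axis=0)
            expected = lab.sum(axis=-1) / on.sum()
            with np.errstate(invalid="ignore", divide="ignore"):
                chi = ((props - expected) ** 2 / expected) * counts[:, None]
            return np.nansum(chi, axis=0)

        obs = float(stat(labels[on][None, :])[0])
        null = stat(perms[:, on])
        p = (np.sum(null >= obs) + 1.0) / (n_perm + 1.0)
        rows.append((c, obs, p, M.shape[0], False))
    return pd.DataFrame(
        rows, columns=["chrom", "statistic", "p_value", "n_windows", "skipped"]
    ).set_index("chrom")


def length_comparison(
    epav_genes: set, non_epav_genes: set, lengths: pd.Series
) -> tuple[float, float, float, float]:
    """Mean gene length of ePAV vs non-ePAV genes with a Welch t-test.

    Returns (mean_epav, mean_non_epav, t_statistic, p_value).
    """
    a = lengths.loc[[g for g in lengths.index if g in epav_genes]].to_numpy(dtype=float)
    b = lengths.loc[[g for g in lengths.index if g in non_epav_genes]].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 genes")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(a.mean()), float(b.mean()), float(t), float(p)
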