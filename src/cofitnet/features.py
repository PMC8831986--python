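"""Ten pairwise similarity/distance features over gene fitness profiles.

For every unordered pair of candidate genes the pipeline computes:
Pearson and Spearman correlation, Euclidean / Manhattan / Minkowski /
Chebyshev distances on the raw profiles, Dice and Jaccard coefficients on
dependency-binarized profiles (score < cutoff), a harmonic-mean similarity on
profiles rescaled to probability vectors, and a plug-in mutual-information
estimate on equal-frequency-binned profiles (bits).

Distances are deliberately left as raw distances — the downstream classifier
consumes them as features and per-feature standardization happens at training
time, so converting them to similarities here would be redundant.

``compute_metric`` is the scalar reference API; ``build_pair_feature_table``
is the vectorized production path.  The two are held together by oracle
tests rather than by sharing code.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import chebyshev as _chebyshev
from scipy.spatial.distance import cityblock as _cityblock
from scipy.spatial.distance import euclidean as _euclidean
from scipy.spatial.distance import minkowski as _minkowski
from scipy.stats import pearsonr, rankdata

__all__ = [
    "FEATURE_NAMES",
    "MetricParams",
    "binarize_dependency",
    "compute_metric",
    "build_pair_feature_table",
]

# fixed column order of the feature table
FEATURE_NAMES = (
    "pearson",
    "spearman",
    "euclidean",
    "dice",
    "manhattan",
    "minkowski",
    "chebyshev",
    "harmonic_mean",
    "jaccard",
    "mutual_information",
)


@dataclass(frozen=True)
class MetricParams:
    """Parameters of the metrics that need one.

    minkowski_order defaults to 3 so the feature is not redundant with the
    p = 1, 2, inf distances already in the set.  mi_bins are equal-frequency
    with ties broken by value order.  binarize_cutoff reuses the dependency
    cutoff: a gene is "depleted" in a line when its score is < cutoff.
    """

    minkowski_order: float = 3.0
    mi_bins: int = 5
    binarize_cutoff: float = -0.5
    constant_vector_impute: float = 0.0

    def validate(self) -> None:
        if self.minkowski_order < 1:
            raise ValueError(f"minkowski_order must be >= 1, got {self.minkowski_order}")
        if self.mi_bins < 2:
            raise ValueError(f"mi_bins must be >= 2, got {self.mi_bins}")


def binarize_dependency(x: np.ndarray, cutoff: float = -0.5) -> np.ndarray:
    """1 where the fitness score is strictly below the cutoff, else 0."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("fitness vector contains non-finite values")
    return (x < cutoff).astype(np.int8)


def equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Assign each value to one of ``bins`` equal-frequency bins.

    Ties are broken by position (stable argsort), so the assignment is a
    deterministic function of the input vector.
    """
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=np.int64)
    ranks[order] = np.arange(len(x))
    return (ranks * bins) // len(x)


def _plugin_mi_bits(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    """Plug-in MI (bits) of two pre-binned integer vectors."""
    joint = np.zeros((bins, bins), dtype=float)
    np.add.at(joint, (a, b), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (pa * pb))
    return float(np.nansum(terms))


def _harmonic_mean_sim(x: np.ndarray, y: np.ndarray) -> float:
    """Harmonic-mean similarity of two profiles as probability vectors.

    Each vector is min-shifted to be nonnegative and normalized to sum 1;
    the similarity is sum_i 2 p_i q_i / (p_i + q_i), with 0/0 terms
    contributing 0.  A constant vector normalizes to nothing and yields 0.
    """
    p = x - x.min()
    q = y - y.min()
    sp, sq = p.sum(), q.sum()
    if sp == 0 or sq == 0:
        return 0.0
    p, q = p / sp, q / sq
    denom = p + q
    mask = denom > 0
    return float(np.sum(2.0 * p[mask] * q[mask] / denom[mask]))


def compute_metric(
    x: np.ndarray,
    y: np.ndarray,
    metric: str,
    params: MetricParams = MetricParams(),
) -> float:
    """Compute one named similarity/distance between two fitness vectors."""
    params.validate()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"vector lengths differ: {x.shape} vs {y.shape}")
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need 1-D vectors of length >= 3")

    if metric == "pearson":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return params.constant_vector_impute
        return float(pearsonr(x, y).statistic)
    if metric == "spearman":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return params.constant_vector_impute
        return float(pearsonr(rankdata(x), rankdata(y)).statistic)
    if metric == "euclidean":
        return float(_euclidean(x, y))
    if metric == "manhattan":
        return float(_cityblock(x, y))
    if metric == "chebyshev":
        return float(_chebyshev(x, y))
    if metric == "minkowski":
        return float(_minkowski(x, y, p=params.minkowski_order))
    if metric in ("dice", "jaccard"):
        a = binarize_dependency(x, params.binarize_cutoff)
        b = binarize_dependency(y, params.binarize_cutoff)
        inter = int(np.sum(a & b))
        if metric == "dice":
            denom = int(a.sum() + b.sum())
            return 2.0 * inter / denom if denom else 0.0
        union = int(np.sum(a | b))
        return inter / union if union else 0.0
    if metric == "harmonic_mean":
        return _harmonic_mean_sim(x, y)
    if metric == "mutual_information":
        a = equal_frequency_bins(x, params.mi_bins)
        b = equal_frequency_bins(y, params.mi_bins)
        return _plugin_mi_bits(a, b, params.mi_bins)
    raise ValueError(f"unknown metric {metric!r}")


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    ia, ib = np.triu_indices(n, k=1)
    return ia, ib


def build_pair_feature_table(
    fitness: pd.DataFrame,
    genes: list[str],
    params: MetricParams = MetricParams(),
) -> pd.DataFrame:
    """One row per unordered gene pair with the ten features, vectorized.

    Rows are ordered by the lexicographic pair key (gene_a < gene_b).
    Constant-profile correlations are imputed with
    ``params.constant_vector_impute``.
    """
    params.validate()
    if len(genes) < 2:
        raise ValueError(f"need >= 2 genes to form pairs, got {len(genes)}")
    missing = [g for g in genes if g not in fitness.index]
    if missing:
        raise KeyError(f"genes absent from fitness matrix: {missing[:5]}")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in candidate list")

    genes = sorted(genes)
    X = fitness.loc[genes].to_numpy(dtype=float)
    n, m = X.shape
    ia, ib = _pair_index(n)

    constant = np.ptp(X, axis=1) == 0

    # correlations via matrix products on standardized rows
    def _corr_matrix(rows: np.ndarray) -> np.ndarray:
        centered = rows - rows.mean(axis=1, keepdims=True)
        sd = centered.std(axis=1)
        safe = np.where(sd == 0, 1.0, sd)
        zs = centered / safe[:, None]
        return (zs @ zs.T) / m

    pear = _corr_matrix(X)[ia, ib]
    ranks = np.apply_along_axis(rankdata, 1, X)
    spear = _corr_matrix(ranks)[ia, ib]
    const_pair = constant[ia] | constant[ib]
    pear = np.where(const_pair, params.constant_vector_impute, np.clip(pear, -1, 1))
    spear = np.where(const_pair, params.constant_vector_impute, np.clip(spear, -1, 1))

    diff = np.abs(X[ia] - X[ib])  # (P, m)
    euclid = np.sqrt(np.sum(diff**2, axis=1))
    manhat = diff.sum(axis=1)
    cheby = diff.max(axis=1)
    minkow = np.sum(diff**params.minkowski_order, axis=1) ** (
        1.0 / params.minkowski_order
    )

    B = (X < params.binarize_cutoff).astype(np.float64)
    inter = (B @ B.T)[ia, ib]
    sizes = B.sum(axis=1)
    size_sum = sizes[ia] + sizes[ib]
    union = size_sum - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dice = np.where(size_sum > 0, 2.0 * inter / size_sum, 0.0)
        jacc = np.where(union > 0, inter / union, 0.0)

    P = X - X.min(axis=1, keepdims=True)
    psum = P.sum(axis=1)
    P = np.divide(P, np.where(psum == 0, 1.0, psum)[:, None])
    p_, q_ = P[ia], P[ib]
    denom = p_ + q_
    with np.errstate(invalid="ignore", divide="ignore"):
        hm_terms = np.where(denom > 0, 2.0 * p_ * q_ / denom, 0.0)
    harm = hm_terms.sum(axis=1)
    zero_prof = psum == 0
    harm = np.where(zero_prof[ia] | zero_prof[ib], 0.0, harm)

    bins = params.mi_bins
    binned = np.empty((n, m), dtype=np.int64)
    for i in range(n):
        binned[i] = equal_frequency_bins(X[i], bins)
    onehot = np.zeros((n, m, bins), dtype=np.float64)
    rows = np.repeat(np.arange(n), m)
    cols = np.tile(np.arange(m), n)
    onehot[rows, cols, binned.ravel()] = 1.0
    mi = np.empty(len(ia))
    chunk = 100_000  # bound peak memory of the P x m x bins intermediates
    for start in range(0, len(ia), chunk):
        sl = slice(start, start + chunk)
        joint = np.einsum("pmi,pmj->pij", onehot[ia[sl]], onehot[ib[sl]]) / m
        pa = joint.sum(axis=2, keepdims=True)
        pb = joint.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            mi_terms = joint * np.log2(joint / (pa * pb))
        mi[sl] = np.nansum(mi_terms, axis=(1, 2))

    gene_arr = np.asarray(genes)
    table = pd.DataFrame(
        {
            "gene_a": gene_arr[ia],
            "gene_b": gene_arr[ib],
            "pearson": pear,
            "spearman": spear,
            "euclidean": euclid,
            "dice": dice,
            "manhattan": manhat,
            "minkowski": minkow,
            "chebyshev": cheby,
            "harmonic_mean": harm,
            "jaccard": jacc,
            "mutual_information": mi,
        }
    )
    table = table.sort_values(["gene_a", "gene_b"], kind="stable").reset_index(drop=True)
    if not np.isfinite(table[list(FEATURE_NAMES)].to_numpy()).all():
        raise AssertionError("non-finite feature values after imputation")
    return table


def count_pairs(n_genes: int) -> int:
    """Size of the unordered pair universe, C(n, 2)."""
    return n_genes * (n_genes - 1) // 2


def enumerate_pairs(genes: list[str]) -> pd.DataFrame:
    """The pair universe as a two-column frame, in the table's row order.

    This is exactly the (gene_a, gene_b) skeleton of
    ``build_pair_feature_table`` without computing any metric, useful to
    meter the pair universe of a large gene list.
    """
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in candidate list")
    genes = sorted(genes)
    ia, ib = _pair_index(len(genes))
    gene_arr = np.asarray(genes)
    return pd.DataFrame({"gene_a": gene_arr[ia], "gene_b": gene_arr[ib]})
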