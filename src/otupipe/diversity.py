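"""Rarefaction, alpha diversity, Bray-Curtis and PCoA.

Estimator conventions follow the mothur ``summary.single`` defaults:
bias-corrected Chao1, the Chao & Lee ACE with rare-class threshold 10,
Shannon in natural log, Simpson as the unbiased dominance
sum(n_i (n_i - 1)) / (N (N - 1)) (smaller = more even), and Good's
coverage 1 - F1/N reported in percent.  Rarefaction is a single
multivariate-hypergeometric draw (subsampling without replacement) at
a recorded seed, not an average over iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from otupipe.cluster import CountTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "rarefy",
    "rarefy_table",
    "chao1",
    "ace",
    "shannon",
    "simpson",
    "goods_coverage",
    "alpha_diversity",
    "bray_curtis",
    "distance_matrix",
    "pcoa",
]


def _counts(x) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    return arr


def rarefy(counts, depth: int = 3000, seed: int | None = None, rng=None) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement
    (one multivariate-hypergeometric draw)."""
    arr = _counts(counts).astype(np.int64)
    total = int(arr.sum())
    if total < depth:
        raise ValueError(f"sample has {total} reads, fewer than rarefaction depth {depth}")
    if total == depth:
        return arr.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(arr, depth)


def rarefy_table(
    table: CountTable, depth: int = 3000, seed: int | None = None, on_short: str = "error"
) -> CountTable:
    """Rarefy every sample of a count table to a common depth.

    ``on_short='drop'`` silently removes samples below the depth;
    the default raises, naming the offending samples.
    """
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    short = list(sums.index[sums < depth])
    if short:
        if on_short == "drop":
            if len(short) == len(table.samples):
                raise ValueError(
                    f"every sample is below the rarefaction depth {depth} "
                    f"(max total {int(sums.max())}); lower the depth"
                )
            table = CountTable(table.counts.drop(index=short), table.groups.drop(index=short), table.label)
        else:
            raise ValueError(f"samples below rarefaction depth {depth}: {short}")
    rows = [rarefy(table.counts.loc[s].values, depth, rng=rng) for s in table.samples]
    counts = pd.DataFrame(rows, index=table.samples, columns=table.otu_ids)
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    return CountTable(counts, table.groups.to_dict(), table.label)


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1))."""
    arr = _counts(counts)
    arr = arr[arr > 0]
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    return float(len(arr) + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def ace(counts, rare_threshold: int = 10) -> float:
    """Chao & Lee abundance-based coverage estimator.

    Classes with counts above the threshold are 'abundant' and counted
    as-is; a negative squared coefficient of variation is clamped at 0.
    When every rare read is a singleton the sample coverage is zero and
    the estimator is undefined; S_obs is returned.
    """
    arr = _counts(counts)
    arr = arr[arr > 0]
    rare = arr[arr <= rare_threshold]
    s_abund = int((arr > rare_threshold).sum())
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return float(len(arr))
    top = sum(i * (i - 1) * int((rare == i).sum()) for i in range(1, rare_threshold + 1))
    gamma2 = max(s_rare / c_ace * top / (n_rare * (n_rare - 1.0)) - 1.0, 0.0) if n_rare > 1 else 0.0
    return float(s_abund + s_rare / c_ace + f1 / c_ace * gamma2)


def shannon(counts) -> float:
    """Shannon index, natural log."""
    arr = _counts(counts).astype(float)
    arr = arr[arr > 0]
    if arr.size == 0:
        return 0.0
    p = arr / arr.sum()
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Unbiased Simpson dominance D = sum n_i(n_i-1) / (N(N-1))."""
    arr = _counts(counts).astype(float)
    arr = arr[arr > 0]
    n = arr.sum()
    if n <= 1:
        return 1.0
    return float((arr * (arr - 1)).sum() / (n * (n - 1)))


def goods_coverage(counts) -> float:
    """Good's coverage (1 - singletons/reads), in percent."""
    arr = _counts(counts)
    n = int(arr.sum())
    if n == 0:
        return 0.0
    f1 = int((arr == 1).sum())
    return float((1.0 - f1 / n) * 100.0)


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample observed OTUs, ACE, Chao1, Shannon, Simpson and
    coverage (%), plus the group label."""
    rows = []
    for s in table.samples:
        v = table.counts.loc[s].values
        rows.append(
            {
                "group": table.groups[s],
                "observed_otus": int((v > 0).sum()),
                "ace": ace(v),
                "chao1": chao1(v),
                "shannon": shannon(v),
                "simpson": simpson(v),
                "coverage": goods_coverage(v),
            }
        )
    return pd.DataFrame(rows, index=table.samples)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2 sum(min) / (sum x + sum y)."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    tot = a.sum() + b.sum()
    if tot == 0:
        return 0.0
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / tot)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative sample dissimilarities with zero diagonal."""

    ids: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self):
        d = self.data
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.ids), columns=list(self.ids))


def distance_matrix(table: CountTable, metric=bray_curtis) -> DistanceMatrix:
    n = len(table.samples)
    m = table.counts.values
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = metric(m[i], m[j])
    return DistanceMatrix(tuple(table.samples), out)


@dataclass(frozen=True)
class OrdinationResult:
    """Sample coordinates on axes ordered by decreasing eigenvalue.

    All eigenvalues (including negative ones, which Bray-Curtis can
    produce) are reported; coordinates and variance proportions use
    the positive eigenvalues only.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportions: np.ndarray


def pcoa(dm: DistanceMatrix, eps: float = 1e-10) -> OrdinationResult:
    """Principal coordinate analysis via Gower double-centering of
    -D^2/2 and eigendecomposition.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue); the sign
    of each axis is fixed so its first nonzero loading is positive.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    scale = max(abs(vals[0]), 1.0)
    pos = vals > eps * scale
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.nonzero(np.abs(col) > eps)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    prop = vals[pos] / vals[pos].sum()
    frame = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"PC{k + 1}" for k in range(coords.shape[1])]
    )
    return OrdinationResult(frame, vals, prop)
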