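"""Correspondence analysis and nonparametric group testing.

Group comparisons follow the study design: four sample sets compared
feature-by-feature with the Friedman test (within-block mid-ranks,
tie-corrected chi-square statistic with k-1 degrees of freedom,
matching R's ``friedman.test``) and the Nemenyi all-pairs post hoc,
whose p-values come from the studentized-range distribution with
infinite degrees of freedom.  Because the four sample sets share no
subjects, blocks are formed by replicate index within group (samples
sorted by id); a Kruskal-Wallis alternative is available for the
global test.  Pairwise results are summarised as a compact letter
display at significance level alpha (groups sharing no letter differ).
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps

__all__ = [
    "CaResult",
    "FriedmanResult",
    "NemenyiResult",
    "GroupTestResult",
    "correspondence_analysis",
    "friedman_test",
    "studentized_range_sf",
    "nemenyi_posthoc",
    "compact_letters",
    "blocks_by_replicate",
    "compare_features",
    "select_major_otus",
    "removal_rate",
]


# ---------------------------------------------------------------- CA


@dataclass(frozen=True)
class CaResult:
    """Correspondence analysis of a nonnegative table (symmetric map:
    principal coordinates = standard coordinates x singular value)."""

    row_coordinates: pd.DataFrame
    col_coordinates: pd.DataFrame
    singular_values: np.ndarray
    total_inertia: float
    proportions: np.ndarray


def correspondence_analysis(table: pd.DataFrame, eps: float = 1e-12) -> CaResult:
    """SVD of the chi-square standardized residuals
    D_r^(-1/2) (P - r c^T) D_c^(-1/2); total inertia equals the
    Pearson chi-square of the table divided by its grand total."""
    m = np.asarray(table, dtype=float)
    if (m < 0).any():
        raise ValueError("table must be nonnegative")
    n = m.sum()
    if n <= 0:
        raise ValueError("table must have a positive grand total")
    r = m.sum(axis=1) / n
    c = m.sum(axis=0) / n
    if (r == 0).any() or (c == 0).any():
        raise ValueError("all-zero row or column in CA input")
    p = m / n
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sig, vt = np.linalg.svd(s, full_matrices=False)
    keep = sig > eps
    sig = sig[keep]
    u = u[:, keep]
    v = vt[keep].T
    # sign convention: first nonzero row loading of each axis positive
    for k in range(u.shape[1]):
        nz = np.nonzero(np.abs(u[:, k]) > eps)[0]
        if nz.size and u[nz[0], k] < 0:
            u[:, k] = -u[:, k]
            v[:, k] = -v[:, k]
    row_std = u / np.sqrt(r)[:, None]
    col_std = v / np.sqrt(c)[:, None]
    axes = [f"CA{k + 1}" for k in range(len(sig))]
    inertia = float((sig**2).sum())
    return CaResult(
        row_coordinates=pd.DataFrame(row_std * sig, index=table.index, columns=axes),
        col_coordinates=pd.DataFrame(col_std * sig, index=table.columns, columns=axes),
        singular_values=sig,
        total_inertia=inertia,
        proportions=sig**2 / inertia if inertia > 0 else sig * 0.0,
    )


# ------------------------------------------------------- group tests


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    df: int
    p_value: float


def _rank_blocks(values) -> np.ndarray:
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise ValueError("need a blocks x groups matrix (unequal block sizes?)")
    n, k = m.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 groups and 2 blocks")
    return sps.rankdata(m, axis=1)


def friedman_test(values) -> FriedmanResult:
    """Friedman rank test of a blocks x groups matrix, with mid-ranks
    for ties and the tie-corrected chi-square statistic (df = k-1)."""
    ranks = _rank_blocks(values)
    n, k = ranks.shape
    col = ranks.sum(axis=0)
    num = 12.0 * ((col - n * (k + 1) / 2.0) ** 2).sum() / (n * k * (k + 1))
    ties = 0.0
    for row in ranks:
        _, cnt = np.unique(row, return_counts=True)
        ties += float((cnt**3 - cnt).sum())
    correction = 1.0 - ties / (n * (k**3 - k))
    if correction <= 0:
        return FriedmanResult(0.0, k - 1, 1.0)
    stat = num / correction
    return FriedmanResult(float(stat), k - 1, float(sps.chi2.sf(stat, k - 1)))


def studentized_range_sf(q: float, k: int) -> float:
    """Upper tail of the studentized range distribution with infinite
    degrees of freedom, by numerical quadrature:
    P(Q > q) = 1 - k Int phi(z) [Phi(z) - Phi(z - q)]^(k-1) dz."""
    if q <= 0:
        return 1.0
    phi, Phi = sps.norm.pdf, sps.norm.cdf

    def integrand(z):
        return phi(z) * (Phi(z) - Phi(z - q)) ** (k - 1)

    cdf, _ = integrate.quad(integrand, -np.inf, np.inf, epsabs=1e-10, epsrel=1e-10)
    return float(min(max(1.0 - k * cdf, 0.0), 1.0))


def compact_letters(p_matrix: pd.DataFrame, alpha: float = 0.05) -> dict[str, str]:
    """Insert-and-absorb compact letter display: groups that differ
    (p <= alpha) share no letter; groups that do not differ share at
    least one."""
    groups = list(p_matrix.index)
    letters: list[set[str]] = [set(groups)]
    for i, gi in enumerate(groups):
        for gj in groups[i + 1:]:
            if p_matrix.loc[gi, gj] <= alpha:
                new = []
                for ls in letters:
                    if gi in ls and gj in ls:
                        new.append(ls - {gi})
                        new.append(ls - {gj})
                    else:
                        new.append(ls)
                # absorb subsets
                letters = [
                    ls
                    for ls in new
                    if ls and not any(ls < other for other in new)
                ]
                # drop duplicates, keep deterministic order
                seen = []
                for ls in letters:
                    if ls not in seen:
                        seen.append(ls)
                letters = seen
    letters.sort(key=lambda ls: min(groups.index(g) for g in ls))
    out = {g: "" for g in groups}
    for ch, ls in zip(string.ascii_lowercase, letters):
        for g in ls:
            out[g] += ch
    return out


@dataclass(frozen=True)
class NemenyiResult:
    p_matrix: pd.DataFrame  # symmetric, unit diagonal
    letters: dict[str, str]
    mean_ranks: pd.Series


def nemenyi_posthoc(values, group_names: Sequence[str] | None = None, alpha: float = 0.05) -> NemenyiResult:
    """All-pairs Nemenyi test on a blocks x groups matrix.

    The statistic for a pair is the mean-rank difference divided by
    sqrt(k(k+1)/(12 n)), referred to the studentized range with k
    groups and infinite df."""
    ranks = _rank_blocks(values)
    n, k = ranks.shape
    if group_names is None:
        group_names = [f"g{j + 1}" for j in range(k)]
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(mean_ranks[i] - mean_ranks[j]) / se
            p[i, j] = p[j, i] = studentized_range_sf(q, k)
    pm = pd.DataFrame(p, index=list(group_names), columns=list(group_names))
    return NemenyiResult(pm, compact_letters(pm, alpha), pd.Series(mean_ranks, index=list(group_names)))


@dataclass(frozen=True)
class GroupTestResult:
    feature: str
    statistic: float
    df: int
    p_value: float
    nemenyi_p: pd.DataFrame
    letters: dict[str, str]


def blocks_by_replicate(
    values: pd.Series, groups: pd.Series, group_order: Sequence[str] | None = None
) -> pd.DataFrame:
    """Arrange per-sample values into a blocks x groups matrix by
    replicate index (sample rank within group, samples sorted by id).
    The four sample sets share no subjects, so this artificial blocking
    is stated prominently; group sizes must be equal."""
    if group_order is None:
        group_order = list(dict.fromkeys(groups))
    cols = {}
    sizes = set()
    for g in group_order:
        ids = sorted(groups.index[groups == g])
        sizes.add(len(ids))
        cols[g] = values.loc[ids].to_numpy()
    if len(sizes) != 1:
        raise ValueError(f"unequal group sizes {sorted(sizes)}: replicate blocking needs balance")
    return pd.DataFrame(cols)


def compare_features(
    abundance: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    group_order: Sequence[str] | None = None,
    method: str = "friedman",
) -> list[GroupTestResult]:
    """Friedman + Nemenyi (or Kruskal-Wallis global test) for every
    column of a samples x features abundance table."""
    if group_order is None:
        group_order = list(dict.fromkeys(groups))
    out = []
    for feature in abundance.columns:
        blocks = blocks_by_replicate(abundance[feature], groups, group_order)
        if method == "friedman":
            fr = friedman_test(blocks.values)
            stat, df, p = fr.statistic, fr.df, fr.p_value
        elif method == "kruskal":
            samples = [abundance[feature][groups == g].to_numpy() for g in group_order]
            kw = sps.kruskal(*samples)
            stat, df, p = float(kw.statistic), len(group_order) - 1, float(kw.pvalue)
        else:
            raise ValueError(f"unknown method {method!r}")
        nem = nemenyi_posthoc(blocks.values, group_order, alpha)
        out.append(GroupTestResult(str(feature), stat, df, p, nem.p_matrix, nem.letters))
    return out


# ------------------------------------------------- table-1 arithmetic


def select_major_otus(
    relative_abundance: pd.DataFrame, groups: pd.Series, threshold: float = 1.0
) -> list[str]:
    """OTUs whose mean relative abundance (%) reaches the threshold in
    at least one sample set."""
    means = relative_abundance.groupby(groups.reindex(relative_abundance.index)).mean()
    keep = means.max(axis=0) >= threshold
    return [c for c in relative_abundance.columns if keep[c]]


def removal_rate(n_removed: int, n_started: int) -> float:
    """Percentage of animals removed from a trial arm, one decimal."""
    if n_started <= 0:
        raise ValueError("n_started must be positive")
    if not (0 <= n_removed <= n_started):
        raise ValueError("need 0 <= n_removed <= n_started")
    return round(100.0 * n_removed / n_started, 1)
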