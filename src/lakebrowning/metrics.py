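"""Community metrics: alpha diversity, rarefaction, accumulation, distances.

Counts are handled as pandas DataFrames (rows = sites, columns = taxa) or
plain arrays.  All binomial-coefficient ratios go through log-gamma
arithmetic so read depths in the 10^5-10^6 range do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

from .errors import (
    DegenerateColumnError,
    EstimatorUndefinedError,
    InvalidDepthError,
    NoSolutionError,
    UndefinedDistanceError,
    ZeroRowError,
)

ALPHA_INDICES = ("richness", "shannon", "simpson", "inv_simpson", "fisher")


def _as_matrix(counts) -> tuple[np.ndarray, list]:
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), list(counts.index)
    arr = np.asarray(counts, dtype=float)
    return arr, list(range(arr.shape[0]))


# ---------------------------------------------------------------------------
# transforms and distances
# ---------------------------------------------------------------------------

def hellinger_transform(counts) -> pd.DataFrame:
    """Square root of relative abundances: cell = sqrt(count / row_sum).

    Each transformed row has unit sum of squares, which makes Euclidean
    distances on the result ecologically well behaved (the Hellinger
    distance of the raw compositions).
    """
    mat, ids = _as_matrix(counts)
    if np.any(mat < 0):
        raise ValueError("counts must be nonnegative")
    row_sums = mat.sum(axis=1)
    zero = np.nonzero(row_sums == 0)[0]
    if zero.size:
        raise ZeroRowError(f"all-zero row(s) for site(s): {[ids[i] for i in zero]}")
    out = np.sqrt(mat / row_sums[:, None])
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return pd.DataFrame(out)


def bray_curtis(matrix) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, d = sum|x-y| / sum(x+y).

    Returns a symmetric site-by-site DataFrame with zero diagonal and
    entries in [0, 1].  Raises if any pair of rows is entirely zero (the
    distance is undefined there).
    """
    mat, ids = _as_matrix(matrix)
    if np.any(mat < 0):
        raise ValueError("entries must be nonnegative")
    row_sums = mat.sum(axis=1)
    zero = np.nonzero(row_sums == 0)[0]
    # a single zero row against a positive row gives d = 1 (fine); two zero
    # rows yield 0/0 and the distance is undefined
    if zero.size >= 2:
        raise UndefinedDistanceError(
            f"Bray-Curtis undefined between all-zero sites {[ids[i] for i in zero]}"
        )
    dm = squareform(pdist(mat, metric="braycurtis"))
    np.fill_diagonal(dm, 0.0)
    return pd.DataFrame(dm, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def fisher_alpha(s_obs: int, n: int) -> float:
    """Fisher's alpha: the root of S = alpha * ln(1 + N / alpha).

    No solution exists when S <= 1 (the log-series needs at least two
    species) or S = N (all singletons, alpha diverges).
    """
    if s_obs <= 1 or s_obs >= n:
        raise NoSolutionError(
            f"Fisher alpha undefined for S={s_obs}, N={n} (need 1 < S < N)"
        )

    def f(a: float) -> float:
        return a * np.log1p(n / a) - s_obs

    # f is increasing: f(0+) -> 0 < S and f(inf) -> N - S > 0
    lo, hi = 1e-10, 1e3
    while f(hi) < 0:
        hi *= 10
        if hi > 1e12:  # pragma: no cover - unreachable for 1 < S < N
            raise NoSolutionError(f"no bracket for S={s_obs}, N={n}")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def alpha_diversity(counts, indices=ALPHA_INDICES) -> pd.DataFrame:
    """Per-site alpha-diversity indices.

    shannon is the natural-log entropy -sum p ln p; simpson is 1 - sum p^2
    (probability two random reads differ); inv_simpson is 1 / sum p^2.
    "Simpson diversity" is ambiguous in the ecological literature, so both
    conventions are reported explicitly.
    """
    if isinstance(indices, str):
        indices = (indices,)
    unknown = set(indices) - set(ALPHA_INDICES)
    if unknown:
        raise ValueError(f"unknown indices: {sorted(unknown)}")
    mat, ids = _as_matrix(counts)
    row_sums = mat.sum(axis=1)
    zero = np.nonzero(row_sums == 0)[0]
    if zero.size:
        raise ZeroRowError(f"all-zero row(s) for site(s): {[ids[i] for i in zero]}")

    out: dict[str, list[float]] = {k: [] for k in indices}
    for row, n in zip(mat, row_sums):
        p = row[row > 0] / n
        s_obs = int((row > 0).sum())
        for key in indices:
            if key == "richness":
                out[key].append(float(s_obs))
            elif key == "shannon":
                out[key].append(float(-(p * np.log(p)).sum()))
            elif key == "simpson":
                out[key].append(float(1.0 - (p**2).sum()))
            elif key == "inv_simpson":
                out[key].append(float(1.0 / (p**2).sum()))
            else:  # fisher
                out[key].append(fisher_alpha(s_obs, int(round(n))))
    return pd.DataFrame(out, index=ids)


@dataclass(frozen=True)
class AceComponents:
    """Chao-Lee ACE estimate with its internal quantities."""

    ace: float
    s_obs: int
    s_abund: int
    s_rare: int
    n_rare: int
    f1: int
    c_ace: float
    gamma2: float


def ace_richness(counts_row, rare_cutoff: int = 10) -> AceComponents:
    """Abundance-based coverage estimator of richness (Chao-Lee).

    Taxa with count <= ``rare_cutoff`` are "rare".  With sample coverage
    C_ace = 1 - F1/N_rare and squared coefficient of variation gamma^2,

        ACE = S_abund + S_rare / C_ace + (F1 / C_ace) * gamma^2.

    C_ace = 0 (every rare taxon a singleton) leaves the estimator undefined
    and raises — no silent fallback to another estimator.
    """
    row = np.asarray(counts_row, dtype=int).ravel()
    row = row[row > 0]
    if row.size == 0:
        raise ZeroRowError("empty count row")
    rare = row[row <= rare_cutoff]
    s_obs = int(row.size)
    s_abund = int((row > rare_cutoff).sum())
    s_rare = int(rare.size)
    if s_rare == 0:
        return AceComponents(float(s_obs), s_obs, s_abund, 0, 0, 0, 1.0, 0.0)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        raise EstimatorUndefinedError(
            "ACE undefined: all rare taxa are singletons (C_ace = 0)"
        )
    i_vals = np.arange(1, rare_cutoff + 1)
    f_i = np.array([(rare == i).sum() for i in i_vals])
    if n_rare > 1:
        gamma2 = (s_rare / c_ace) * (i_vals * (i_vals - 1) * f_i).sum() / (
            n_rare * (n_rare - 1)
        ) - 1.0
    else:
        gamma2 = 0.0
    gamma2 = max(gamma2, 0.0)
    ace = s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2
    return AceComponents(float(ace), s_obs, s_abund, s_rare, n_rare, f1, c_ace, gamma2)


# ---------------------------------------------------------------------------
# rarefaction and accumulation
# ---------------------------------------------------------------------------

def _log_choose(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy_expected(counts_row, depth: int) -> float:
    """Expected richness in a random subsample of ``depth`` reads.

    Hurlbert's formula E[S_n] = sum_k [1 - C(N - N_k, n) / C(N, n)],
    evaluated with log-binomials for overflow safety.
    """
    row = np.asarray(counts_row, dtype=int).ravel()
    row = row[row > 0]
    if row.size == 0:
        raise ZeroRowError("empty count row")
    n_total = int(row.sum())
    if not 1 <= depth <= n_total:
        raise InvalidDepthError(f"depth must be in [1, {n_total}], got {depth}")
    keep = n_total - row >= depth
    terms = np.zeros(row.size)
    if keep.any():
        terms[keep] = np.exp(
            _log_choose(n_total - row[keep], depth) - _log_choose(n_total, depth)
        )
    return float((1.0 - terms).sum())


def rarefy_subsample(counts, depth: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Subsample each site without replacement to a common depth.

    When ``depth`` is omitted it defaults to the minimum row sum — the
    common ecological convention of rarefying to the shallowest sample.
    """
    mat, ids = _as_matrix(counts)
    imat = np.asarray(np.rint(mat), dtype=np.int64)
    row_sums = imat.sum(axis=1)
    if depth is None:
        depth = int(row_sums.min())
    bad = np.nonzero(row_sums < depth)[0]
    if bad.size:
        raise InvalidDepthError(
            f"depth {depth} exceeds reads at site(s) {[ids[i] for i in bad]}"
        )
    rng = np.random.default_rng(seed)
    out = np.vstack(
        [rng.multivariate_hypergeometric(row, depth) for row in imat]
    )
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class AccumulationCurve:
    """Expected richness vs number of sites accumulated."""

    m: np.ndarray
    expected_richness: np.ndarray
    mode: str = "exact"


def species_accum_exact(counts) -> AccumulationCurve:
    """Analytical species accumulation curve over sites.

    E[S(m)] = sum_k [1 - C(T - T_k, m) / C(T, m)] where T is the number of
    sites and T_k the number of sites occupied by taxon k — the exact mean
    over all random site orderings, no permutations needed.
    """
    mat, _ = _as_matrix(counts)
    t_sites = mat.shape[0]
    occ = (mat > 0).sum(axis=0)
    occ = occ[occ > 0]
    ms = np.arange(1, t_sites + 1)
    curve = np.empty(t_sites)
    for i, m in enumerate(ms):
        keep = t_sites - occ >= m
        terms = np.zeros(occ.size)
        if keep.any():
            terms[keep] = np.exp(
                _log_choose(t_sites - occ[keep], m) - _log_choose(t_sites, m)
            )
        curve[i] = (1.0 - terms).sum()
    return AccumulationCurve(ms, curve, "exact")


# ---------------------------------------------------------------------------
# CDOM browning index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PcaIndex:
    """PCA of absorption spectra: per-site scores and variance fractions.

    PC1 is the "browning index": its sign is fixed so scores correlate
    positively with mean absorbance.
    """

    scores: pd.DataFrame
    variance_fractions: np.ndarray


def cdom_pca_index(spectra, n_components: int = 6, scale: bool = True) -> PcaIndex:
    """Principal components of (optionally standardized) absorption spectra."""
    from sklearn.decomposition import PCA

    mat, ids = _as_matrix(spectra)
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need at least 2 sites and 2 wavelengths")
    if scale:
        sd = mat.std(axis=0, ddof=0)
        const = np.nonzero(sd == 0)[0]
        if const.size:
            raise DegenerateColumnError(
                f"constant wavelength column(s) at index {const.tolist()}"
            )
        work = (mat - mat.mean(axis=0)) / sd
    else:
        work = mat - mat.mean(axis=0)
    k = min(n_components, min(work.shape) - 0, work.shape[1], work.shape[0])
    pca = PCA(n_components=min(k, min(work.shape)))
    scores = pca.fit_transform(work)
    fractions = pca.explained_variance_ratio_.copy()
    # orient PC1 toward increasing mean absorbance
    mean_abs = mat.mean(axis=1)
    r = np.corrcoef(scores[:, 0], mean_abs)[0, 1]
    if np.isfinite(r) and r < 0:
        scores[:, 0] *= -1.0
    cols = [f"pc{i + 1}" for i in range(scores.shape[1])]
    return PcaIndex(pd.DataFrame(scores, index=ids, columns=cols), fractions)
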