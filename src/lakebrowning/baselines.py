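"""Monotonic comparators: RDA, variance partitioning, distance decay, hump test.

These are the standard linear-model analyses that the nonmonotonic surface
models are contrasted against.  RDA here is the regression step that
matters for variance accounting: multivariate OLS of the (Hellinger
transformed, column-centered) community matrix on scaled predictors, with
R^2 as the ratio of fitted to total sum of squares and the Ezekiel
adjustment 1 - (1 - R^2)(n - 1)/(n - p - 1).

Smooth-curve (GAM-style) alpha-diversity fits are deliberately replaced by
a linear-vs-quadratic AIC comparison: the scientific claim under test is
the existence of an interior diversity peak, which the quadratic captures
without penalized-spline machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import CollinearityError, DegenerateRegressionError

# ---------------------------------------------------------------------------
# RDA and variance partitioning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RdaFit:
    r2: float
    adj_r2: float
    n: int
    p: int


def _as_array(a) -> np.ndarray:
    return a.to_numpy(dtype=float) if isinstance(a, pd.DataFrame) else np.asarray(a, float)


def rda_r2(y, x, scale: bool = True, allow_rank_deficient: bool = False) -> RdaFit:
    """Redundancy-analysis variance explained.

    ``y`` is the (Hellinger-transformed) community matrix, ``x`` the
    predictor table; both are centered, ``x`` optionally z-scored.  By
    default rank-deficient predictors raise rather than being silently
    dropped; with ``allow_rank_deficient=True`` the fit projects onto the
    predictor column space (small singular values truncated) and the
    effective rank replaces p in the adjustment — variance partitioning
    needs this so a duplicated predictor set lands entirely in the shared
    fraction instead of erroring.
    """
    ymat = _as_array(y)
    xmat = _as_array(x)
    if xmat.ndim == 1:
        xmat = xmat[:, None]
    n, p = xmat.shape
    xc = xmat - xmat.mean(axis=0)
    if scale:
        sd = xc.std(axis=0, ddof=1)
        bad = np.nonzero(sd == 0)[0]
        if bad.size:
            raise CollinearityError(f"constant predictor column(s) {bad.tolist()}")
        xc = xc / sd
    sv = np.linalg.svd(xc, compute_uv=False)
    rank = int((sv > sv[0] * 1e-9).sum()) if sv.size else 0
    if rank < p:
        if not allow_rank_deficient:
            raise CollinearityError(
                f"predictor matrix is rank deficient ({p} columns, rank {rank})"
            )
        p = rank
    if n <= p + 1:
        raise CollinearityError(f"need n > p + 1 (n={n}, p={p})")
    yc = ymat - ymat.mean(axis=0)
    ss_tot = float((yc**2).sum())
    if ss_tot == 0:
        raise DegenerateRegressionError("community matrix has zero variance")
    coef, *_ = np.linalg.lstsq(xc, yc, rcond=1e-9)
    fitted = xc @ coef
    r2 = float((fitted**2).sum() / ss_tot)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return RdaFit(r2, float(adj), n, p)


@dataclass
class VariancePartition:
    """Unique/shared adjusted-R^2 fractions of named predictor sets.

    ``fractions`` maps each nonempty subset of set names (as a sorted
    tuple) to its exclusive fraction; ``residual`` completes the unit sum.
    Negative fractions are a known artifact of the adjustment and are
    reported, not clipped.
    """

    fractions: dict[tuple[str, ...], float]
    residual: float
    subset_adj_r2: dict[tuple[str, ...], float]

    def unique(self, name: str) -> float:
        return self.fractions[(name,)]

    def total(self) -> float:
        return sum(self.fractions.values()) + self.residual


def variance_partition(y, x_sets: dict, scale: bool = True,
                       adjusted: bool = True) -> VariancePartition:
    """Partition community variance over 2-3 predictor sets.

    (Adjusted) R^2 is computed for every nonempty union of the sets; the
    exclusive fraction of each subset S of set names is obtained by
    inclusion-exclusion, so all fractions plus the residual sum to one
    exactly.  ``adjusted=False`` uses raw R^2 (useful for exactness checks;
    raw R^2 is monotone under adding predictors, the adjusted version is
    not).
    """
    names = list(x_sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("x_sets must contain 2 or 3 predictor sets")
    mats = {k: _as_array(v) for k, v in x_sets.items()}
    mats = {k: (m[:, None] if m.ndim == 1 else m) for k, m in mats.items()}

    r2_of: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            xmat = np.hstack([mats[k] for k in combo])
            fit = rda_r2(y, xmat, scale=scale, allow_rank_deficient=True)
            r2_of[frozenset(combo)] = fit.adj_r2 if adjusted else fit.r2

    # Venn-cell value of subset S by Moebius inversion: with
    # f(C) = R2(all) - R2(complement of C) (the variance reachable only
    # through sets in C), v(S) = sum_{C subset S} (-1)^(|S|-|C|) f(C).
    all_set = frozenset(names)
    fractions: dict[tuple[str, ...], float] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            s = frozenset(combo)
            value = 0.0
            for rr in range(len(combo) + 1):
                for sub in combinations(combo, rr):
                    comp = all_set - frozenset(sub)
                    value += (-1) ** (len(combo) - rr) * (
                        r2_of[all_set] - r2_of[comp]
                    )
            fractions[tuple(sorted(combo))] = value
    residual = 1.0 - r2_of[all_set]
    subset_adj = {tuple(sorted(k)): v for k, v in r2_of.items() if k}
    return VariancePartition(fractions, float(residual), subset_adj)


# ---------------------------------------------------------------------------
# distance decay
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceDecay:
    slope: float
    intercept: float
    r2: float
    p: float
    n_pairs: int


def distance_decay(community_dist, geographic_dist, n_perm: int = 999,
                   seed: int = 0) -> DistanceDecay:
    """OLS of community on geographic distance with a Mantel permutation p.

    Both matrices must be symmetric and conformable; the regression runs
    over unordered pairs.  The null permutes rows and columns of the
    geographic matrix jointly (the exchangeable units are sites, not
    pairs); p is one-sided on the Pearson correlation.
    """
    dc = _as_array(community_dist)
    dg = _as_array(geographic_dist)
    if dc.shape != dg.shape or dc.shape[0] != dc.shape[1]:
        raise ValueError("matrices must be square and conformable")
    if not (np.allclose(dc, dc.T) and np.allclose(dg, dg.T)):
        raise ValueError("matrices must be symmetric")
    n = dc.shape[0]
    iu = np.triu_indices(n, k=1)
    yv, xv = dc[iu], dg[iu]
    if np.all(xv == xv[0]):
        raise DegenerateRegressionError("constant geographic distances")
    slope, intercept = np.polyfit(xv, yv, 1)
    pred = slope * xv + intercept
    ss_tot = ((yv - yv.mean()) ** 2).sum()
    r2 = float(1.0 - ((yv - pred) ** 2).sum() / ss_tot) if ss_tot > 0 else 0.0
    obs_r = np.corrcoef(xv, yv)[0, 1]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = dg[np.ix_(perm, perm)][iu]
        if np.corrcoef(xp, yv)[0, 1] >= obs_r:
            hits += 1
    return DistanceDecay(float(slope), float(intercept), r2,
                         (1 + hits) / (n_perm + 1), len(yv))


# ---------------------------------------------------------------------------
# alpha-diversity hump test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HumpTest:
    aic_linear: float
    aic_quadratic: float
    winner: str
    peak: float | None
    coef_linear: tuple
    coef_quadratic: tuple


def alpha_hump_test(alpha_values, gradient) -> HumpTest:
    """Linear vs quadratic OLS of alpha diversity on the gradient.

    AIC = n ln(SSE/n) + 2k with k the coefficient count; the quadratic's
    vertex -b/(2a) is reported as the diversity peak only when the
    parabola is concave (a < 0) and the vertex lies inside the observed
    gradient range.
    """
    a = np.asarray(alpha_values, dtype=float)
    g = np.asarray(gradient, dtype=float)
    if len(a) != len(g) or len(a) < 6:
        raise ValueError("need >= 6 paired observations")
    if np.all(g == g[0]):
        raise DegenerateRegressionError("zero-variance gradient")
    n = len(a)

    def _aic(deg: int):
        coef = np.polyfit(g, a, deg)
        sse = float(((np.polyval(coef, g) - a) ** 2).sum())
        k = deg + 1
        sse = max(sse, 1e-300)  # guard exact fits
        return n * np.log(sse / n) + 2 * k, coef

    aic1, c1 = _aic(1)
    aic2, c2 = _aic(2)
    winner = "quadratic" if aic2 < aic1 else "linear"
    peak = None
    if winner == "quadratic" and c2[0] < 0:
        vertex = -c2[1] / (2 * c2[0])
        if g.min() < vertex < g.max():
            peak = float(vertex)
    return HumpTest(float(aic1), float(aic2), winner, peak,
                    tuple(c1), tuple(c2))
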