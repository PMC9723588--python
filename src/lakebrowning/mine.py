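"""MINE statistics: MIC, MAS, permutation tests, and taxon screening.

The maximal information coefficient (MIC) is the largest normalized mutual
information achievable by gridding a scatter of n points, over all grids
with ``cols * rows <= B(n) = n^alpha`` (both axis orientations evaluated).
The maximum asymmetry score (MAS) is the largest absolute difference between
the characteristic matrix and its transpose and measures deviation from
monotonicity: monotone relationships grid symmetrically, unimodal ones do
not.

The grid search uses the ApproxMaxMI scheme: one axis is equipartitioned,
the other optimized exactly by a dynamic program over "clumps" (runs of
points that no optimal partition ever splits), with a superclump cap
controlled by the clump factor c.  The DP solves its subproblem exactly;
the test suite checks it against exhaustive search.

``mine_screen`` applies this to a taxa table: each taxon's relative
abundance is screened against the browning gradient, p-values come from
seeded permutations of the gradient, q-values from Benjamini-Hochberg, and
each significant taxon is classified monotone (MAS < cutoff) or
nonmonotone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from ._mine_dp import (
    _axis_best_mi,
    _char_entries,
    _mas_from_entries,
    _mic_from_entries,
)
from .errors import (
    DegenerateVariableError,
    InvalidPartitionError,
    InvalidPError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MineConfig:
    """Parameters of the MINE analysis.

    ``alpha_exponent`` sets the grid budget B(n) = floor(n^alpha);
    ``clump_factor`` caps the DP's superclump count at c * max_columns;
    ``mic_cutoff`` and ``mas_monotone_cutoff`` are the significance and
    monotonicity thresholds used by :func:`mine_screen`.
    """

    alpha_exponent: float = 0.6
    clump_factor: int = 15
    n_perm: int = 999
    mic_cutoff: float = 0.3
    mas_monotone_cutoff: float = 0.05
    fdr_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_exponent < 1.0:
            raise ValueError("alpha_exponent must be in (0, 1)")
        if self.clump_factor < 1:
            raise ValueError("clump_factor must be >= 1")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")

    def budget(self, n: int) -> int:
        return int(np.floor(n**self.alpha_exponent))


@dataclass(frozen=True)
class CharacteristicMatrix:
    """Normalized characteristic matrix M[cols, rows] of one variable pair."""

    entries: dict[tuple[int, int], float]
    n: int
    budget: int

    def mic(self) -> float:
        return max(self.entries.values(), default=0.0)

    def mas(self) -> float:
        best = 0.0
        for (a, b), v in self.entries.items():
            w = self.entries.get((b, a))
            if w is not None:
                best = max(best, abs(v - w))
        return best


def _plogp_table(n: int) -> np.ndarray:
    tab = np.zeros(n + 1)
    i = np.arange(1, n + 1)
    tab[1:] = (i / n) * np.log2(i / n)
    return tab


def _equipartition(sorted_vals: np.ndarray, q: int) -> tuple[np.ndarray, int]:
    """Adaptive equipartition of sorted values into <= q bins, ties together."""
    n = len(sorted_vals)
    rows = np.empty(n, dtype=np.int64)
    i, curr, h = 0, 0, 0.0
    rowsize = n / q
    while i < n:
        j = i + 1
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        s = j - i
        if h != 0.0 and curr < q - 1 and abs(h + s - rowsize) >= abs(h - rowsize):
            curr += 1
            h = 0.0
            rowsize = (n - i) / (q - curr)
        rows[i:j] = curr
        h += s
        i = j
    return rows, curr + 1


class _PairPrep:
    """Reusable sort/partition state for MIC on (x, y) and its permutations."""

    def __init__(self, x: np.ndarray, y: np.ndarray, config: MineConfig):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D and of equal length")
        n = len(x)
        if np.all(x == x[0]) or np.all(y == y[0]):
            raise DegenerateVariableError("constant variable: MIC undefined")
        self.n = n
        self.b = config.budget(n)
        self.c = config.clump_factor
        self.sigma = np.argsort(x, kind="stable")
        self.tau = np.argsort(y, kind="stable")
        xs, ys = x[self.sigma], y[self.tau]
        self.new_x = np.ones(n, dtype=np.uint8)
        self.new_x[1:] = (xs[1:] != xs[:-1]).astype(np.uint8)
        self.new_y = np.ones(n, dtype=np.uint8)
        self.new_y[1:] = (ys[1:] != ys[:-1]).astype(np.uint8)
        self.ybins, self.ybin_q = self._levels(ys, self.tau)
        self.xbins, self.xbin_q = self._levels(xs, self.sigma)
        self.plogp = _plogp_table(n)
        self.entries = np.empty((self.b + 1, self.b + 1))
        a = np.arange(self.b + 1, dtype=float)
        self.log2min = np.log2(np.maximum(np.minimum.outer(a, a), 2.0))

    def _levels(self, sorted_vals, order):
        """Row assignments (original index order) for each distinct bin count."""
        n = self.n
        seen: set[int] = set()
        bins, qs = [], []
        for q in range(2, max(self.b // 2, 2) + 1):
            rows_sorted, q_eff = _equipartition(sorted_vals, q)
            if q_eff < 2 or q_eff in seen:
                continue
            seen.add(q_eff)
            full = np.empty(n, dtype=np.int64)
            full[order] = rows_sorted
            bins.append(full)
            qs.append(q_eff)
        if not bins:
            return np.zeros((0, n), dtype=np.int64), np.zeros(0, dtype=np.int64)
        return np.vstack(bins), np.asarray(qs, dtype=np.int64)

    def entries_for(self, perm: np.ndarray | None = None) -> np.ndarray:
        """Raw characteristic entries for (x[perm], y); None = identity."""
        if perm is None:
            ymap, xmap = self.sigma, self.tau
        else:
            pinv = np.argsort(perm)
            ymap = pinv[self.sigma]
            xmap = perm[self.tau]
        _char_entries(
            ymap, xmap, self.new_x, self.new_y,
            self.ybins, self.ybin_q, self.xbins, self.xbin_q,
            self.b, self.c, self.plogp, self.entries,
        )
        return self.entries

    def mic(self, perm: np.ndarray | None = None) -> float:
        return float(_mic_from_entries(self.entries_for(perm), self.log2min))

    def mic_mas(self) -> tuple[float, float]:
        e = self.entries_for(None)
        return (
            float(_mic_from_entries(e, self.log2min)),
            float(_mas_from_entries(e, self.log2min)),
        )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def optimize_x_axis(
    x, y_rows, max_columns: int, c: int = 15
) -> dict[int, float]:
    """Best mutual information per x-column budget, given a fixed y-partition.

    ``y_rows`` assigns each point to a row of the fixed partition.  Returns
    {l: I_l} in bits for l = 2..max_columns, where I_l is the maximum over
    clump-respecting partitions of the x axis into at most l columns; the
    values are nondecreasing in l.
    """
    x = np.asarray(x, dtype=float)
    y_rows = np.asarray(y_rows, dtype=np.int64)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 points")
    if len(y_rows) != n:
        raise ValueError("x and y_rows must have equal length")
    uniq = np.unique(y_rows)
    if len(uniq) < 2:
        raise InvalidPartitionError("fixed y partition must have >= 2 rows")
    if max_columns < 2:
        raise ValueError("max_columns must be >= 2")
    # relabel rows densely
    remap = {v: i for i, v in enumerate(uniq)}
    dense = np.array([remap[v] for v in y_rows], dtype=np.int64)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    new_x = np.ones(n, dtype=np.uint8)
    new_x[1:] = (xs[1:] != xs[:-1]).astype(np.uint8)
    res = _axis_best_mi(
        dense[order], new_x, len(uniq), max_columns, c, _plogp_table(n)
    )
    return {l: float(res[l]) for l in range(2, max_columns + 1)}


def characteristic_matrix(x, y, config: MineConfig | None = None) -> CharacteristicMatrix:
    """Normalized characteristic matrix over all grids with cols*rows <= B(n)."""
    config = config or MineConfig()
    x = np.asarray(x, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 points")
    prep = _PairPrep(x, y, config)
    raw = prep.entries_for(None)
    entries = {}
    for a in range(2, prep.b + 1):
        for b in range(2, prep.b + 1):
            if raw[a, b] >= 0.0:
                entries[(a, b)] = float(raw[a, b] / np.log2(min(a, b)))
    return CharacteristicMatrix(entries, prep.n, prep.b)


def mic_mas(x, y, config: MineConfig | None = None) -> tuple[float, float]:
    """(MIC, MAS) of one variable pair."""
    config = config or MineConfig()
    if len(np.asarray(x)) < 10:
        raise ValueError("need at least 10 points")
    return _PairPrep(np.asarray(x, float), np.asarray(y, float), config).mic_mas()


def permutation_pvalue(
    x, y, n_perm: int | None = None, seed: int | None = None,
    config: MineConfig | None = None,
) -> float:
    """Permutation p-value for MIC: p = (1 + #{MIC_perm >= MIC_obs}) / (n_perm + 1).

    The gradient ``x`` is permuted, which is exact-level under
    exchangeability; the add-one convention keeps p in (0, 1].
    """
    config = config or MineConfig()
    n_perm = config.n_perm if n_perm is None else n_perm
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    seed = config.seed if seed is None else seed
    prep = _PairPrep(np.asarray(x, float), np.asarray(y, float), config)
    observed = prep.mic()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(prep.n)
        if prep.mic(perm) >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidPError("need a nonempty 1-D p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InvalidPError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hochberg_fwer(pvalues) -> np.ndarray:
    """Hochberg's step-up family-wise adjusted p-values (available behind a flag)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise InvalidPError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate((p[order] * (m - np.arange(m)))[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def mine_screen(
    counts,
    gradient,
    config: MineConfig | None = None,
    *,
    correction: str = "bh",
) -> pd.DataFrame:
    """Screen every taxon's abundance against the browning gradient.

    Counts are converted to relative abundances per site so sequencing depth
    cannot masquerade as signal.  Permutations of the gradient are shared
    across taxa (one seeded set), which keeps the screen O(n_taxa * n_perm)
    and the per-taxon levels exact.

    Returns a DataFrame indexed by taxon with columns
    ``mic, mas, spearman_sign, p, q, class`` where class is ``monotone``
    (q < fdr_level, MIC >= mic_cutoff, MAS < mas_monotone_cutoff),
    ``nonmonotone`` (same but MAS >= cutoff) or ``not_significant``.
    """
    config = config or MineConfig()
    if isinstance(counts, pd.DataFrame):
        taxa = list(counts.columns)
        mat = counts.to_numpy(dtype=float)
    else:
        mat = np.asarray(counts, dtype=float)
        taxa = [f"t{j}" for j in range(mat.shape[1])]
    g = np.asarray(gradient, dtype=float)
    if len(g) != mat.shape[0]:
        raise ValueError("gradient length must equal the number of sites")
    rel = mat / mat.sum(axis=1)[:, None]

    rng = np.random.default_rng(config.seed)
    perms = [rng.permutation(len(g)) for _ in range(config.n_perm)]

    rows = []
    for j, taxon in enumerate(taxa):
        y = rel[:, j]
        if np.all(y == y[0]):
            logger.warning("taxon %s is constant; reported as not_significant", taxon)
            rows.append((taxon, np.nan, np.nan, 0, np.nan, np.nan, "not_significant"))
            continue
        prep = _PairPrep(g, y, config)
        mic, mas = prep.mic_mas()
        hits = sum(1 for perm in perms if prep.mic(perm) >= mic)
        p = (1 + hits) / (config.n_perm + 1)
        rho = spearmanr(g, y).statistic
        sign = 0 if not np.isfinite(rho) else int(np.sign(rho))
        rows.append((taxon, mic, mas, sign, p, np.nan, ""))

    out = pd.DataFrame(
        rows, columns=["taxon", "mic", "mas", "spearman_sign", "p", "q", "class"]
    ).set_index("taxon")
    tested = out["p"].notna()
    if tested.any():
        adjust = bh_fdr if correction == "bh" else hochberg_fwer
        out.loc[tested, "q"] = adjust(out.loc[tested, "p"].to_numpy())
        sig = tested & (out["q"] < config.fdr_level) & (out["mic"] >= config.mic_cutoff)
        out.loc[tested, "class"] = "not_significant"
        out.loc[sig & (out["mas"] < config.mas_monotone_cutoff), "class"] = "monotone"
        out.loc[sig & (out["mas"] >= config.mas_monotone_cutoff), "class"] = "nonmonotone"
    return out
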