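"""Ridge/valley ("guardrail") detection on beta-diversity surfaces.

A regime threshold shows up on the pairwise-distance surface as a ridge
crossing the diagonal: sites just below and just above the threshold are
already far apart compositionally.  This module formalizes the visual
reading of such surfaces into an explicit, reproducible rule: average the
surface over a near-diagonal band to get a turnover profile t(g), then run
prominence-filtered peak detection on it.  Every constant of the rule is a
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InvalidBandError
from .surface import MeshSurface


@dataclass
class TurnoverProfile:
    """Near-diagonal mean of a surface: t(g_u) = mean S[u, v], 0 < |u-v| <= k.

    ``surface_min``/``surface_range`` record the value scale of the surface
    the profile was read from; detection thresholds are expressed relative
    to that scale so that a flat near-diagonal profile on an otherwise
    structured surface cannot promote its own noise ripples to ridges.
    """

    g: np.ndarray
    t: np.ndarray
    band_k: int
    surface_range: float | None = None
    surface_min: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gradient": self.g, "turnover": self.t})


@dataclass(frozen=True)
class Feature:
    """One detected ridge or valley."""

    position: float
    prominence: float
    edge: bool = False


@dataclass
class ThresholdReport:
    """Ridges (thresholds) and valleys (stable regimes) along one descriptor."""

    ridges: list[Feature]
    valleys: list[Feature]
    baseline: float
    params: dict

    def to_dict(self) -> dict:
        return {
            "ridges": [asdict(f) for f in self.ridges],
            "valleys": [asdict(f) for f in self.valleys],
            "baseline": self.baseline,
            "params": self.params,
        }


def turnover_profile(surface: MeshSurface, band_k: int = 3) -> TurnoverProfile:
    """Cross-diagonal turnover at each gradient position.

    t(g_u) averages the surface cells S[u-j, u+j] for j = 1..band_k — the
    predicted distances between site pairs *straddling* g_u at small
    gradient lags.  This is the formal version of reading the surface "from
    a point bordering the diagonal": a community threshold at g_u makes
    every straddling pair distant no matter how small the lag, so t peaks
    exactly at the threshold.  Endpoints, where no straddling pair exists,
    fall back to the adjacent off-diagonal cell (one-sided band).  The
    diagonal itself is excluded (self-distances are zero by construction).
    """
    n = len(surface.axis)
    if band_k < 1 or band_k >= n:
        raise InvalidBandError(f"band_k must be in [1, {n - 1}], got {band_k}")
    if n <= 2 * band_k:
        raise InvalidBandError(f"axis length {n} must exceed 2*band_k={2 * band_k}")
    s = surface.values
    t = np.empty(n)
    for u in range(n):
        vals = [s[u - j, u + j] for j in range(1, band_k + 1)
                if u - j >= 0 and u + j < n]
        if not vals:  # axis endpoint: one-sided read
            vals = [s[u, u + 1]] if u == 0 else [s[u, u - 1]]
        t[u] = float(np.mean(vals))
    return TurnoverProfile(surface.axis.copy(), t, band_k,
                           float(s.max() - s.min()), float(s.min()))


def _merge_close(positions, prominences, min_sep: float):
    """Greedily keep the most prominent features at least min_sep apart."""
    order = np.argsort(-np.asarray(prominences))
    kept: list[int] = []
    for i in order:
        if all(abs(positions[i] - positions[j]) >= min_sep for j in kept):
            kept.append(i)
    kept.sort(key=lambda i: positions[i])
    return kept


def detect_ridges_valleys(
    profile: TurnoverProfile,
    baseline: float,
    min_prominence_frac: float = 0.1,
    min_separation_frac: float = 0.05,
    ridge_level_frac: float = 0.3,
) -> ThresholdReport:
    """Prominence- and level-filtered peak detection on the turnover profile.

    All thresholds are relative to the surface's full value range R (so
    detection is invariant to affine rescaling of the surface; the
    profile's own range is used when no surface scale is attached):

    * a *ridge* is a local maximum of t with prominence >=
      ``min_prominence_frac * R`` whose turnover level rises at least
      ``ridge_level_frac * R`` above the surface minimum — i.e. a gradient
      value where a single near-diagonal step already produces a sizeable
      fraction of the surface's whole beta-diversity range, the signature
      of a regime shift.  Smoothly accumulating (monotone) turnover never
      reaches that level next to the diagonal.
    * a *valley* is a local minimum of t with the same prominence bound
      whose level stays below the ridge line — an interval where the
      community does not shift substantially.

    The surface-wide mean ``baseline`` beta-diversity is recorded in the
    report for interpretation.  Features closer along the gradient than
    ``min_separation_frac`` * gradient range are merged, keeping the more
    prominent.  Maxima at the axis endpoints are reported but flagged
    ``edge=True`` (their band is one-sided).  A flat profile yields an
    empty report.
    """
    t, g = profile.t, profile.g
    if len(t) < 5:
        raise InvalidBandError("profile needs >= 5 points")
    t_range = float(t.max() - t.min())
    ref_range = profile.surface_range if profile.surface_range else t_range
    ref_min = profile.surface_min if profile.surface_range else float(t.min())
    g_range = float(g[-1] - g[0])
    params = _params(min_prominence_frac, min_separation_frac, ridge_level_frac)
    if t_range == 0 or ref_range == 0:
        return ThresholdReport([], [], baseline, params)
    min_prom = min_prominence_frac * ref_range
    min_sep = min_separation_frac * g_range
    ridge_line = ref_min + ridge_level_frac * ref_range

    def _features(signal: np.ndarray, keep_mask: np.ndarray) -> list[Feature]:
        idx, props = find_peaks(signal, prominence=min_prom)
        positions = [float(g[i]) for i in idx]
        proms = [float(p) for p in props["prominences"]]
        edges = [False] * len(idx)
        # endpoint features: boundary prominence = height above the lowest
        # point reached before any higher point going inward
        for end, step in ((0, 1), (len(signal) - 1, -1)):
            run_min = signal[end]
            i = end + step
            while 0 <= i < len(signal) and signal[i] <= signal[end]:
                run_min = min(run_min, signal[i])
                i += step
            prom = signal[end] - run_min
            if prom >= min_prom:
                positions.append(float(g[end]))
                proms.append(float(prom))
                edges.append(True)
        feats = [
            Feature(p, pr, e)
            for p, pr, e in zip(positions, proms, edges)
            if keep_mask[np.argmin(np.abs(g - p))]
        ]
        if not feats:
            return []
        kept = _merge_close([f.position for f in feats],
                            [f.prominence for f in feats], min_sep)
        return sorted((feats[i] for i in kept), key=lambda f: f.position)

    ridges = _features(t, t >= ridge_line)
    valleys = _features(-t, t < ridge_line)
    return ThresholdReport(ridges, valleys, float(baseline), params)


def _params(prom: float, sep: float, level: float) -> dict:
    return {
        "min_prominence_frac": prom,
        "min_separation_frac": sep,
        "ridge_level_frac": level,
    }


def guardrail_summary(reports: dict[str, ThresholdReport],
                      ranges: dict[str, tuple[float, float]]) -> dict:
    """Per-descriptor guardrail positions and the regimes they delimit.

    ``ranges`` gives each descriptor's (min, max) gradient span; ridge
    positions partition it into regime intervals.  The result is plain
    JSON-serializable data.
    """
    if not reports:
        raise ValueError("need at least one report")
    summary: dict = {}
    for name, report in reports.items():
        lo, hi = ranges[name]
        cuts = [f.position for f in report.ridges if lo < f.position < hi]
        edges = [lo, *cuts, hi]
        summary[name] = {
            "thresholds": cuts,
            "valleys": [f.position for f in report.valleys],
            "baseline": report.baseline,
            "regimes": [[a, b] for a, b in zip(edges[:-1], edges[1:])],
        }
    return summary
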