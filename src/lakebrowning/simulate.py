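"""Synthetic lake-browning communities with known regime structure.

This module generates site-by-taxon count tables along a one-dimensional
"browning" gradient (think TOC in mg C L^-1 or CDOM absorbance), together
with per-site metadata and CDOM-like absorption spectra.  The generator's
defining feature is that the ground truth is known: taxa respond to the
gradient with one of four shapes (logistic up/down, Gaussian unimodal, or a
sharp step at a regime threshold), and community composition additionally
carries *regime structure* — below a convergence point the gradient is cut
into segments by thresholds tau, and within each segment sites fall into one
of several alternative states marked by disjoint sets of indicator taxa.
Above the convergence point a single state exists, emulating the convergence
of alternative community trajectories at high browning.

Counts are multinomial draws at fixed sequencing depth, so every downstream
estimator (rarefaction, ACE, Bray-Curtis surfaces, MINE screening) can be
validated against this known truth without any external data.

How alternative states manifest compositionally is not something a field
survey pins down; the disjoint indicator-taxa construction used here is this
package's explicit operationalization of "alternative community states" and
is documented as such in the methods note.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import (
    DegenerateProfileError,
    InvalidDesignError,
    InvalidMixError,
    InvalidProfileError,
)

SHAPES = ("monotone_up", "monotone_down", "unimodal", "step")
Shape = Literal["monotone_up", "monotone_down", "unimodal", "step"]

WAVELENGTHS = np.arange(400, 751)  # nm, 1-nm steps, 351 values


# ---------------------------------------------------------------------------
# design dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientDesign:
    """Layout of sites along the browning gradient.

    Parameters
    ----------
    n_sites:
        Number of sites (>= 2).
    g_min, g_max:
        Gradient bounds in browning units (e.g. mg C L^-1).
    spacing:
        ``uniform_random`` draws sites uniformly in ``[g_min, g_max]`` (then
        sorts them); ``equally_spaced`` returns an arithmetic sequence
        including both bounds.
    seed:
        Seed for the random spacing mode.
    """

    n_sites: int
    g_min: float
    g_max: float
    spacing: Literal["uniform_random", "equally_spaced"] = "uniform_random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise InvalidDesignError(f"n_sites must be >= 2, got {self.n_sites}")
        if not self.g_min < self.g_max:
            raise InvalidDesignError(
                f"g_min must be < g_max, got [{self.g_min}, {self.g_max}]"
            )
        if self.spacing not in ("uniform_random", "equally_spaced"):
            raise InvalidDesignError(f"unknown spacing {self.spacing!r}")


@dataclass(frozen=True)
class TaxonResponse:
    """Expected-abundance response of one taxon to the gradient.

    ``location`` is the logistic midpoint, Gaussian optimum, or step
    threshold; ``width`` the corresponding scale; ``amplitude`` the maximal
    expected relative abundance (before community-wide normalization).
    ``sign`` is only used by ``step`` (+1 steps up with browning).
    """

    shape: Shape
    location: float
    width: float
    amplitude: float
    sign: int = 1

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise InvalidDesignError(f"unknown shape {self.shape!r}")
        if self.width <= 0 or self.amplitude <= 0:
            raise InvalidDesignError("width and amplitude must be positive")

    def expected(self, g: np.ndarray) -> np.ndarray:
        """Expected (unnormalized) abundance at gradient values ``g``."""
        g = np.asarray(g, dtype=float)
        z = (g - self.location) / self.width
        if self.shape == "monotone_up":
            return self.amplitude / (1.0 + np.exp(-z))
        if self.shape == "monotone_down":
            return self.amplitude / (1.0 + np.exp(z))
        if self.shape == "unimodal":
            return self.amplitude * np.exp(-0.5 * z * z)
        # step: a steep logistic, rising (sign=+1) or falling (sign=-1)
        return self.amplitude / (1.0 + np.exp(-self.sign * z))


@dataclass(frozen=True)
class RegimeModel:
    """Regime thresholds and alternative-state layout.

    ``thresholds`` are the tau values cutting the gradient; below
    ``convergence_threshold`` each inter-threshold segment hosts
    ``n_alt_states`` alternative states, above it exactly one state exists.
    Each (segment, state) regime — and the converged high-browning state —
    owns ``state_taxa_per_regime`` indicator taxa.
    """

    thresholds: tuple[float, ...]
    n_alt_states: int
    convergence_threshold: float
    state_taxa_per_regime: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        t = tuple(self.thresholds)
        if list(t) != sorted(t) or len(set(t)) != len(t):
            raise InvalidDesignError("thresholds must be strictly increasing")
        if self.n_alt_states < 1:
            raise InvalidDesignError("n_alt_states must be >= 1")
        if t and self.convergence_threshold < max(t):
            raise InvalidDesignError(
                "convergence_threshold must be >= max(thresholds)"
            )
        if self.state_taxa_per_regime < 1:
            raise InvalidDesignError("state_taxa_per_regime must be >= 1")
        object.__setattr__(self, "thresholds", t)

    @property
    def low_boundaries(self) -> list[float]:
        """Thresholds strictly below the convergence point."""
        return [t for t in self.thresholds if t < self.convergence_threshold]

    @property
    def n_low_segments(self) -> int:
        return len(self.low_boundaries) + 1

    @property
    def n_states(self) -> int:
        """Total number of distinct states, including the converged one."""
        return self.n_low_segments * self.n_alt_states + 1

    @property
    def converged_state(self) -> int:
        """State id of the single high-browning state."""
        return self.n_low_segments * self.n_alt_states


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset (for recovery tests)."""

    thresholds: list[float]
    convergence_threshold: float
    responses: list[TaxonResponse]
    states: list[int]
    n_alt_states: int
    state_taxa_per_regime: int
    state_fraction: float

    def to_dict(self) -> dict:
        return {
            "thresholds": list(self.thresholds),
            "convergence_threshold": self.convergence_threshold,
            "responses": [asdict(r) for r in self.responses],
            "states": [int(s) for s in self.states],
            "n_alt_states": self.n_alt_states,
            "state_taxa_per_regime": self.state_taxa_per_regime,
            "state_fraction": self.state_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            thresholds=list(d["thresholds"]),
            convergence_threshold=d["convergence_threshold"],
            responses=[TaxonResponse(**r) for r in d["responses"]],
            states=list(d["states"]),
            n_alt_states=d["n_alt_states"],
            state_taxa_per_regime=d["state_taxa_per_regime"],
            state_fraction=d["state_fraction"],
        )


@dataclass
class SyntheticDataset:
    """A generated community dataset plus its ground truth.

    ``counts`` is sites x taxa (nonnegative integers, rows summing to the
    configured depth); ``sites`` carries site_id, gradient_value, state_id
    and depth; ``spectra`` is sites x wavelengths (400-750 nm).
    """

    counts: pd.DataFrame
    sites: pd.DataFrame
    spectra: pd.DataFrame
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# generator operations
# ---------------------------------------------------------------------------

def make_gradient(design: GradientDesign) -> np.ndarray:
    """Per-site gradient values for a :class:`GradientDesign`."""
    if design.spacing == "equally_spaced":
        return np.linspace(design.g_min, design.g_max, design.n_sites)
    rng = np.random.default_rng(design.seed)
    g = rng.uniform(design.g_min, design.g_max, size=design.n_sites)
    return np.sort(g)


def _shape_counts(n_taxa: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n_taxa over the shape classes."""
    raw = proportions * n_taxa
    counts = np.floor(raw).astype(int)
    short = n_taxa - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def make_taxon_responses(
    n_taxa: int,
    shape_mix: Sequence[float] | dict[str, float],
    regime: RegimeModel,
    bounds: tuple[float, float],
    seed: int = 0,
    *,
    step_width_frac: float = 0.01,
    width_frac_range: tuple[float, float] = (0.10, 0.25),
) -> list[TaxonResponse]:
    """Draw a catalog of per-taxon gradient responses.

    ``shape_mix`` gives proportions over (monotone_up, monotone_down,
    unimodal, step); it must be nonnegative and sum to 1.  Unimodal optima
    are drawn with density peaked mid-gradient so realized richness humps at
    intermediate browning; step locations are drawn from the regime's
    thresholds; step widths default to 1% of the gradient range so regime
    shifts stay steep but differentiable.
    """
    if isinstance(shape_mix, dict):
        mix = np.array([shape_mix.get(s, 0.0) for s in SHAPES], dtype=float)
    else:
        mix = np.asarray(shape_mix, dtype=float)
    if mix.shape != (4,):
        raise InvalidMixError("shape_mix must give proportions for 4 shapes")
    if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
        raise InvalidMixError(
            f"shape proportions must be nonnegative and sum to 1, got {mix}"
        )
    g_min, g_max = bounds
    if not g_min < g_max:
        raise InvalidDesignError("bounds must satisfy g_min < g_max")
    span = g_max - g_min
    counts = _shape_counts(n_taxa, mix)
    rng = np.random.default_rng(seed)

    responses: list[TaxonResponse] = []
    for shape, k in zip(SHAPES, counts):
        for _ in range(k):
            amp = float(rng.lognormal(mean=0.0, sigma=1.0))
            width = float(rng.uniform(*width_frac_range) * span)
            if shape in ("monotone_up", "monotone_down"):
                loc = float(rng.uniform(g_min + 0.1 * span, g_max - 0.1 * span))
                responses.append(TaxonResponse(shape, loc, width, amp))
            elif shape == "unimodal":
                # optima concentrated mid-gradient: truncated normal
                mid, sd = g_min + 0.5 * span, span / 6.0
                a, b = (g_min - mid) / sd, (g_max - mid) / sd
                loc = float(
                    truncnorm.rvs(a, b, loc=mid, scale=sd, random_state=rng)
                )
                responses.append(TaxonResponse(shape, loc, width, amp))
            else:  # step
                if regime.thresholds:
                    loc = float(rng.choice(np.asarray(regime.thresholds)))
                else:
                    loc = float(rng.uniform(g_min, g_max))
                sign = int(rng.choice([-1, 1]))
                responses.append(
                    TaxonResponse(shape, loc, step_width_frac * span, amp, sign)
                )
    return responses


def assign_states(
    g: np.ndarray, regime: RegimeModel, seed: int | None = None
) -> np.ndarray:
    """Assign each site to a community state.

    Sites at or above the convergence threshold all share the single
    converged state; below it, a site's segment is fixed by the thresholds
    and its alternative state is drawn uniformly (seeded) among the segment's
    ``n_alt_states`` states.  State ids are ``segment * n_alt_states + alt``
    for low-browning sites and :attr:`RegimeModel.converged_state` above.
    """
    g = np.asarray(g, dtype=float)
    rng = np.random.default_rng(regime.seed if seed is None else seed)
    bounds = np.asarray(regime.low_boundaries)
    states = np.empty(len(g), dtype=int)
    # one stream of alternative-state draws, in site order, for determinism
    alts = rng.integers(0, regime.n_alt_states, size=len(g))
    for i, gi in enumerate(g):
        if gi >= regime.convergence_threshold:
            states[i] = regime.converged_state
        else:
            seg = int(np.searchsorted(bounds, gi, side="right"))
            states[i] = seg * regime.n_alt_states + alts[i]
    return states


def expected_profiles(
    g: np.ndarray,
    states: np.ndarray,
    responses: Sequence[TaxonResponse],
    regime: RegimeModel,
    state_fraction: float = 0.45,
) -> pd.DataFrame:
    """Per-site expected relative-abundance profiles over all taxa.

    The community at each site is a mixture: a fraction ``state_fraction`` of
    expected relative abundance goes to the indicator taxa of the site's
    state (split equally), the rest to the gradient-response taxa in
    proportion to their response functions.  Rows sum to 1 exactly.
    """
    g = np.asarray(g, dtype=float)
    states = np.asarray(states, dtype=int)
    if len(g) != len(states):
        raise InvalidDesignError("g and states must have equal length")
    if not 0.0 <= state_fraction < 1.0:
        raise InvalidDesignError("state_fraction must be in [0, 1)")

    resp = np.column_stack([r.expected(g) for r in responses])
    row_sums = resp.sum(axis=1)
    dead = np.nonzero(row_sums <= 0)[0]
    if dead.size:
        raise DegenerateProfileError(
            f"site(s) {dead.tolist()} have zero total expected abundance"
        )
    resp = (1.0 - state_fraction) * resp / row_sums[:, None]

    n_state_taxa = regime.n_states * regime.state_taxa_per_regime
    state_block = np.zeros((len(g), n_state_taxa))
    per_taxon = state_fraction / regime.state_taxa_per_regime
    for i, s in enumerate(states):
        lo = s * regime.state_taxa_per_regime
        state_block[i, lo : lo + regime.state_taxa_per_regime] = per_taxon

    profiles = np.hstack([resp, state_block])
    # exact renormalization guards against float drift
    profiles /= profiles.sum(axis=1)[:, None]
    cols = [f"t{j:04d}" for j in range(len(responses))] + [
        f"s{s}_{k}"
        for s in range(regime.n_states)
        for k in range(regime.state_taxa_per_regime)
    ]
    return pd.DataFrame(profiles, columns=cols)


def sample_counts(
    profiles: pd.DataFrame | np.ndarray, depth: int, seed: int = 0
) -> pd.DataFrame:
    """Multinomial read sampling: each site row sums to exactly ``depth``."""
    if depth < 1:
        raise InvalidDesignError("depth must be >= 1")
    p = np.asarray(profiles, dtype=float)
    if np.any(p < 0):
        raise InvalidProfileError("profiles must be nonnegative")
    p = p / p.sum(axis=1)[:, None]
    rng = np.random.default_rng(seed)
    counts = np.vstack([rng.multinomial(depth, row) for row in p])
    if isinstance(profiles, pd.DataFrame):
        return pd.DataFrame(counts, index=profiles.index, columns=profiles.columns)
    return pd.DataFrame(counts)


def make_spectra(
    g: np.ndarray,
    a400_slope: float = 0.2,
    s_decay: float = 0.015,
    noise_sd: float = 0.005,
    seed: int = 0,
    *,
    a400_intercept: float = 0.05,
    floor: float = 1e-6,
) -> pd.DataFrame:
    """CDOM-like absorption spectra, 400-750 nm at 1-nm steps.

    The noiseless spectrum is the classic exponential decay
    ``a(lambda) = a400(g) * exp(-s_decay * (lambda - 400))`` with the 400-nm
    absorption increasing linearly in the browning gradient.  Gaussian noise
    is added and clipped at ``floor`` so absorbance stays strictly positive
    (log/PCA stages downstream require it).
    """
    if s_decay <= 0:
        raise InvalidDesignError("s_decay must be > 0")
    g = np.asarray(g, dtype=float)
    a400 = a400_intercept + a400_slope * g
    base = a400[:, None] * np.exp(-s_decay * (WAVELENGTHS - 400.0))[None, :]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        base = base + rng.normal(0.0, noise_sd, size=base.shape)
    spectra = np.maximum(base, floor)
    return pd.DataFrame(spectra, columns=[str(w) for w in WAVELENGTHS])


# ---------------------------------------------------------------------------
# scenario assembly and I/O
# ---------------------------------------------------------------------------

#: Default shape mixture: nonmonotone responses dominate, as they do along
#: real browning gradients (unimodal-heavy, with a minority of step taxa).
DEFAULT_SHAPE_MIX = (0.20, 0.20, 0.45, 0.15)


def simulate_dataset(
    n_sites: int = 80,
    n_taxa: int = 300,
    g_min: float = 0.0,
    g_max: float = 12.0,
    thresholds: Sequence[float] = (3.0, 7.0),
    n_alt_states: int = 2,
    convergence_threshold: float = 7.0,
    state_taxa_per_regime: int = 8,
    depth: int = 10_000,
    shape_mix: Sequence[float] = DEFAULT_SHAPE_MIX,
    state_fraction: float = 0.45,
    spacing: str = "uniform_random",
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a full dataset; defaults are the standard synthetic scenario.

    The standard scenario has 80 sites on a gradient spanning 0-12 browning
    units, 300 taxa, regime thresholds at tau = 3 and 7 with two alternative
    states below the convergence point at 7, and a constant sequencing depth
    of 10,000 reads per site.  ``n_taxa`` counts *all* taxa; the regime's
    indicator taxa are carved out of it and the remainder get gradient
    responses.
    """
    ss = np.random.SeedSequence(seed)
    s_grad, s_resp, s_state, s_counts, s_spec = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    )
    design = GradientDesign(n_sites, g_min, g_max, spacing, seed=s_grad)
    regime = RegimeModel(
        tuple(float(t) for t in thresholds),
        n_alt_states,
        float(convergence_threshold),
        state_taxa_per_regime,
        seed=s_state,
    )
    n_state_taxa = regime.n_states * regime.state_taxa_per_regime
    if n_taxa <= n_state_taxa:
        raise InvalidDesignError(
            f"n_taxa={n_taxa} must exceed the {n_state_taxa} indicator taxa"
        )
    g = make_gradient(design)
    responses = make_taxon_responses(
        n_taxa - n_state_taxa, shape_mix, regime, (g_min, g_max), seed=s_resp
    )
    states = assign_states(g, regime)
    profiles = expected_profiles(g, states, responses, regime, state_fraction)
    counts = sample_counts(profiles, depth, seed=s_counts)
    site_ids = [f"site{(i + 1):03d}" for i in range(n_sites)]
    counts.index = pd.Index(site_ids, name="site_id")
    spectra = make_spectra(g, seed=s_spec)
    spectra.index = counts.index
    sites = pd.DataFrame(
        {
            "site_id": site_ids,
            "gradient_value": g,
            "state_id": states,
            "depth": depth,
        }
    ).set_index("site_id")
    truth = SyntheticTruth(
        thresholds=list(regime.thresholds),
        convergence_threshold=regime.convergence_threshold,
        responses=responses,
        states=[int(s) for s in states],
        n_alt_states=n_alt_states,
        state_taxa_per_regime=state_taxa_per_regime,
        state_fraction=state_fraction,
    )
    return SyntheticDataset(counts, sites, spectra, truth)


_FLOAT_FMT = "%.10g"


def write_dataset(dataset: SyntheticDataset, directory: str | os.PathLike) -> None:
    """Write counts/sites/spectra TSVs and the truth JSON to ``directory``.

    The files round-trip exactly through :func:`read_dataset`.
    """
    d = os.fspath(directory)
    if not os.path.isdir(d):
        raise IOError(f"not a writable directory: {d}")
    dataset.counts.to_csv(os.path.join(d, "counts.tsv"), sep="\t")
    dataset.sites.to_csv(
        os.path.join(d, "sites.tsv"), sep="\t", float_format=_FLOAT_FMT
    )
    dataset.spectra.to_csv(
        os.path.join(d, "spectra.tsv"), sep="\t", float_format=_FLOAT_FMT
    )
    with open(os.path.join(d, "truth.json"), "w") as fh:
        json.dump(dataset.truth.to_dict(), fh, indent=1)


def read_dataset(directory: str | os.PathLike) -> SyntheticDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    d = os.fspath(directory)
    counts = pd.read_csv(os.path.join(d, "counts.tsv"), sep="\t", index_col=0)
    sites = pd.read_csv(os.path.join(d, "sites.tsv"), sep="\t", index_col=0)
    spectra = pd.read_csv(os.path.join(d, "spectra.tsv"), sep="\t", index_col=0)
    spectra.columns = [str(c) for c in spectra.columns]
    with open(os.path.join(d, "truth.json")) as fh:
        truth = SyntheticTruth.from_dict(json.load(fh))
    return SyntheticDataset(counts, sites, spectra, truth)


def monotonicity_class(response: TaxonResponse) -> str:
    """Generative monotonicity of a response shape.

    Logistic and step responses are monotone over the whole axis; a Gaussian
    unimodal response is nonmonotone.  Note that the *realized* relative
    abundance a taxon shows in a community divides the response by the
    site's total expected abundance, which can change monotonicity; use
    :func:`realized_monotonicity` for the curve a screen actually sees.
    """
    return "nonmonotone" if response.shape == "unimodal" else "monotone"


def rank_reversal_score(y_along_gradient: np.ndarray) -> float:
    """How nonmonotone a curve is, measured in rank space.

    The curve (values ordered by increasing gradient) is rank-transformed
    and the smaller of its total rises and total falls is divided by the
    rank range: 0 for a strictly monotone curve, approaching 1 for a
    balanced unimodal one.  Ranks are used because rank-based dependence
    statistics are amplitude-blind — a tiny absolute wiggle on a plateau is
    a large excursion in rank space, and vice versa.
    """
    from scipy.stats import rankdata

    r = rankdata(np.asarray(y_along_gradient, dtype=float))
    span = r.max() - r.min()
    if span == 0:
        return 0.0
    d = np.diff(r)
    return float(min(d[d > 0].sum(), -d[d < 0].sum()) / span)


def realized_monotonicity(
    y_along_gradient: np.ndarray,
    monotone_below: float = 0.05,
    nonmonotone_above: float = 0.3,
    min_branch_frac: float = 0.2,
) -> str:
    """Classify a noiseless curve as clearly monotone, clearly nonmonotone,
    or ambiguous.

    "Clearly monotone" means the rank-reversal score is below
    ``monotone_below``; "clearly nonmonotone" requires the score above
    ``nonmonotone_above`` *and* both branches around the rank extremum to
    hold at least ``min_branch_frac`` of the sites (a reversal carried by a
    handful of edge sites is not resolvable by any grid statistic at these
    sample sizes).  Everything else is ambiguous and should be excluded
    from recovery scoring.
    """
    from scipy.stats import rankdata

    y = np.asarray(y_along_gradient, dtype=float)
    score = rank_reversal_score(y)
    if score < monotone_below:
        return "monotone"
    r = rankdata(y)
    d = np.diff(r)
    k = int(np.argmax(r)) if d[d > 0].sum() >= -d[d < 0].sum() else int(np.argmin(r))
    balance = min(k, len(r) - 1 - k) / len(r)
    if score > nonmonotone_above and balance >= min_branch_frac:
        return "nonmonotone"
    return "ambiguous"
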