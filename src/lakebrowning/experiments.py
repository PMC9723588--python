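"""Canned validation experiments on the synthetic study conditions.

These functions run the pipeline's scientific claims end to end on the
standard synthetic scenario (80 sites, 300 taxa, thresholds at 3 and 7,
two alternative states, depth 10,000) and its regime-free monotone
counterpart.  They are used by the test suite and the acceptance script;
they are also the quickest way for a user to see what the package does.
"""

from __future__ import annotations

import numpy as np

from . import simulate
from .metrics import bray_curtis
from .mine import MineConfig, mine_screen
from .surface import (
    build_pair_dataset,
    evaluate_model,
    fit_gradient_boost,
    fit_polynomial,
    predict_meshgrid,
    split_train_test,
)
from .thresholds import detect_ridges_valleys, turnover_profile

#: Generator settings for the regime-free, purely monotone control scenario.
MONOTONE_SCENARIO = dict(
    thresholds=(), n_alt_states=1, convergence_threshold=0.0,
    state_fraction=0.0, shape_mix=(0.5, 0.5, 0.0, 0.0),
)

#: Problem sizes used by the experiments (standard scenario throughout).
MAX_GRID = 300
BAND_K = 5


def detect_thresholds_for_seed(seed: int, **scenario) -> list[float]:
    """Simulate -> Bray-Curtis -> GBT surface -> turnover -> ridge positions."""
    ds = simulate.simulate_dataset(seed=seed, **scenario)
    g = ds.sites["gradient_value"].to_numpy()
    pairs = build_pair_dataset(g, bray_curtis(ds.counts))
    train, _ = split_train_test(pairs, 0.8, seed=seed)
    gbt = fit_gradient_boost(train, seed=seed)
    mesh = predict_meshgrid(gbt, g, max_grid=MAX_GRID)
    report = detect_ridges_valleys(turnover_profile(mesh, BAND_K), mesh.baseline)
    return [f.position for f in report.ridges]


def threshold_recovery(seeds, true_taus=(3.0, 7.0), tol: float = 0.5) -> dict:
    """Fraction of seeds in which each true threshold is recovered."""
    hits = {tau: 0 for tau in true_taus}
    detected = []
    for seed in seeds:
        ridges = detect_thresholds_for_seed(int(seed))
        detected.append(ridges)
        for tau in true_taus:
            hits[tau] += any(abs(r - tau) <= tol for r in ridges)
    n = len(list(seeds))
    return {
        "per_tau_rate": {tau: hits[tau] / n for tau in true_taus},
        "min_rate": min(hits[tau] / n for tau in true_taus),
        "detected": detected,
    }


def false_positive_rate(seeds) -> float:
    """Fraction of regime-free monotone runs with any detected ridge."""
    fp = sum(bool(detect_thresholds_for_seed(int(s), **MONOTONE_SCENARIO))
             for s in seeds)
    return fp / len(list(seeds))


def r2_contrast(seed: int) -> dict:
    """GBT vs degree-1 polynomial test R^2 on the standard scenario."""
    ds = simulate.simulate_dataset(seed=seed)
    g = ds.sites["gradient_value"].to_numpy()
    pairs = build_pair_dataset(g, bray_curtis(ds.counts))
    train, test = split_train_test(pairs, 0.8, seed=seed)
    gbt_model = fit_gradient_boost(train, seed=seed)
    gbt = evaluate_model(gbt_model, test)
    poly = evaluate_model(fit_polynomial(train, 1), test)
    mesh = predict_meshgrid(gbt_model, g, MAX_GRID)
    return {
        "gbt_test_r2": gbt.test_r2,
        "poly1_test_r2": poly.test_r2,
        "gap": gbt.test_r2 - poly.test_r2,
        "surface_baseline_mean": mesh.baseline,
    }


def linear_agreement(seed: int, n_sites: int = 60) -> dict:
    """GBT vs degree-1 polynomial on a purely linear distance relationship.

    Distances are generated directly as a linear function of the two sites'
    gradient values plus symmetric noise, so the polynomial is the correct
    model and the boosted trees have no nonmonotonic structure to exploit:
    the two test R^2 values should agree closely.
    """
    rng = np.random.default_rng(seed)
    g = np.sort(rng.uniform(0.0, 12.0, n_sites))
    d = 0.2 + 0.02 * (g[:, None] + g[None, :])
    noise = rng.normal(0.0, 0.05, size=(n_sites, n_sites))
    d = np.clip(d + (noise + noise.T) / 2, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    pairs = build_pair_dataset(g, d)
    train, test = split_train_test(pairs, 0.8, seed=seed)
    gbt = evaluate_model(fit_gradient_boost(train, seed=seed), test)
    poly = evaluate_model(fit_polynomial(train, 1), test)
    return {
        "gbt_test_r2": gbt.test_r2,
        "poly1_test_r2": poly.test_r2,
        "gap": abs(gbt.test_r2 - poly.test_r2),
    }


def classification_recovery(seed: int, n_perm: int = 99) -> dict:
    """MINE monotonicity classes vs ground truth on noiseless abundances.

    The screen sees each taxon's noiseless expected relative abundance (the
    generative response divided by the site total, i.e. what composition
    actually exposes).  Ground truth per taxon comes from
    :func:`lakebrowning.simulate.realized_monotonicity` on the same curve;
    taxa whose curve is ambiguous at rank level are excluded.
    """
    ds = simulate.simulate_dataset(seed=seed)
    g = ds.sites["gradient_value"].to_numpy()
    truth = ds.truth
    regime = simulate.RegimeModel(
        tuple(truth.thresholds), truth.n_alt_states,
        truth.convergence_threshold, truth.state_taxa_per_regime,
    )
    profiles = simulate.expected_profiles(
        g, np.asarray(truth.states), truth.responses, regime,
        truth.state_fraction,
    )
    resp_cols = [c for c in profiles.columns if c.startswith("t")]
    cfg = MineConfig(n_perm=n_perm, seed=seed)
    screened = mine_screen(profiles[resp_cols], g, cfg)
    order = np.argsort(g)
    ok = total = 0
    for name in resp_cols:
        want = simulate.realized_monotonicity(profiles[name].to_numpy()[order])
        if want == "ambiguous":
            continue
        total += 1
        ok += screened.loc[name, "class"] == want
    return {"accuracy": ok / total, "n_scored": total,
            "n_taxa": len(resp_cols), "screen": screened}
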