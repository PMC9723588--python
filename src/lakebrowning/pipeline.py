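"""Pipeline orchestration: simulate -> metrics -> mine -> surface -> thresholds.

A :class:`RunConfig` (flat key-value mapping, YAML on disk) drives the
stages; one global seed fans out to per-stage seeds through a stable hash
so stage-level reruns reproduce exactly.  Every artifact is TSV or JSON, so
runs are diffable; a manifest records stages, seeds, resolved defaults and
timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from . import baselines, metrics, mine, simulate, surface, thresholds
from .errors import ConfigError, StageError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "alpha", "mine", "surface", "thresholds", "varpart")

_FLOAT_FMT = "%.10g"


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Flat, validated pipeline configuration.

    Simulation keys mirror :func:`lakebrowning.simulate.simulate_dataset`;
    ``counts_path``/``sites_path`` switch the pipeline onto external data
    instead.  Unknown keys are rejected up front.
    """

    # data source: either simulation parameters or existing files
    counts_path: str | None = None
    sites_path: str | None = None
    spectra_path: str | None = None
    gradient_column: str = "gradient_value"
    # simulation
    n_sites: int = 80
    n_taxa: int = 300
    g_min: float = 0.0
    g_max: float = 12.0
    thresholds: tuple = (3.0, 7.0)
    n_alt_states: int = 2
    convergence_threshold: float = 7.0
    state_taxa_per_regime: int = 8
    depth: int = 10_000
    shape_mix: tuple = simulate.DEFAULT_SHAPE_MIX
    state_fraction: float = 0.45
    # mine
    mine_n_perm: int = 199
    mic_cutoff: float = 0.3
    mas_monotone_cutoff: float = 0.05
    fdr_level: float = 0.05
    # surface
    train_frac: float = 0.8
    gbt_rounds: int = 300
    gbt_depth: int = 3
    gbt_learning_rate: float = 0.1
    gbt_reg_lambda: float = 1.0
    poly_degree: int = 1
    max_grid: int = 300
    # thresholds: band of 5 grid steps ~ 0.2 gradient units at the default
    # grid, a little over one typical site spacing in the standard scenario
    band_k: int = 5
    min_prominence_frac: float = 0.1
    min_separation_frac: float = 0.05
    ridge_level_frac: float = 0.3
    # global
    seed: int = 0
    outdir: str = "lakebrowning_run"

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()
        })
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            mapping = yaml.safe_load(fh) or {}
        if not isinstance(mapping, dict):
            raise ConfigError(f"config file {path} must hold a flat mapping")
        return cls.from_mapping(mapping)

    def validate(self) -> None:
        if (self.counts_path is None) != (self.sites_path is None):
            raise ConfigError("counts_path and sites_path must be given together")
        if not 0 < self.train_frac < 1:
            raise ConfigError("train_frac must be in (0, 1)")
        if self.mine_n_perm < 99:
            raise ConfigError("mine_n_perm must be >= 99")
        if self.band_k < 1:
            raise ConfigError("band_k must be >= 1")


def _write_json(path: str, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


class PipelineRun:
    """Executes stages in dependency order inside an output directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = config.outdir
        os.makedirs(self.outdir, exist_ok=True)
        self.manifest: dict = {
            "seed": config.seed,
            "config": {f.name: getattr(config, f.name) for f in fields(config)},
            "stages": {},
        }
        self._dataset: simulate.SyntheticDataset | None = None

    # -- data access -------------------------------------------------------
    def _load(self):
        cfg = self.config
        if cfg.counts_path is not None:
            counts = pd.read_csv(cfg.counts_path, sep="\t", index_col=0)
            sites = pd.read_csv(cfg.sites_path, sep="\t", index_col=0)
            spectra = None
            if cfg.spectra_path:
                spectra = pd.read_csv(cfg.spectra_path, sep="\t", index_col=0)
            return counts, sites, spectra
        dataset = self._ensure_simulated()
        return dataset.counts, dataset.sites, dataset.spectra

    def _ensure_simulated(self) -> simulate.SyntheticDataset:
        if self._dataset is None:
            cfg = self.config
            self._dataset = simulate.simulate_dataset(
                n_sites=cfg.n_sites, n_taxa=cfg.n_taxa, g_min=cfg.g_min,
                g_max=cfg.g_max, thresholds=cfg.thresholds,
                n_alt_states=cfg.n_alt_states,
                convergence_threshold=cfg.convergence_threshold,
                state_taxa_per_regime=cfg.state_taxa_per_regime,
                depth=cfg.depth, shape_mix=cfg.shape_mix,
                state_fraction=cfg.state_fraction,
                seed=stage_seed(cfg.seed, "simulate"),
            )
        return self._dataset

    # -- stages ------------------------------------------------------------
    def stage_simulate(self) -> dict:
        dataset = self._ensure_simulated()
        simulate.write_dataset(dataset, self.outdir)
        return {"files": ["counts.tsv", "sites.tsv", "spectra.tsv", "truth.json"]}

    def stage_alpha(self) -> dict:
        counts, sites, _ = self._load()
        alpha = metrics.alpha_diversity(
            counts, ("richness", "shannon", "simpson", "inv_simpson")
        )
        ace = []
        for _, row in counts.iterrows():
            try:
                ace.append(metrics.ace_richness(row.to_numpy()).ace)
            except metrics.EstimatorUndefinedError:
                ace.append(np.nan)
        alpha["ace"] = ace
        alpha.index.name = "site_id"
        alpha.to_csv(os.path.join(self.outdir, "alpha.tsv"), sep="\t",
                     float_format=_FLOAT_FMT)
        g = sites[self.config.gradient_column].to_numpy(float)
        hump = baselines.alpha_hump_test(alpha["richness"].to_numpy(), g)
        result = {
            "aic_linear": hump.aic_linear,
            "aic_quadratic": hump.aic_quadratic,
            "winner": hump.winner,
            "peak": hump.peak,
        }
        _write_json(os.path.join(self.outdir, "alpha_hump.json"), result)
        return {"files": ["alpha.tsv", "alpha_hump.json"], "hump_winner": hump.winner}

    def stage_mine(self) -> dict:
        counts, sites, _ = self._load()
        cfg = self.config
        mcfg = mine.MineConfig(
            n_perm=cfg.mine_n_perm, mic_cutoff=cfg.mic_cutoff,
            mas_monotone_cutoff=cfg.mas_monotone_cutoff,
            fdr_level=cfg.fdr_level, seed=stage_seed(cfg.seed, "mine"),
        )
        g = sites[cfg.gradient_column].to_numpy(float)
        result = mine.mine_screen(counts, g, mcfg)
        result.to_csv(os.path.join(self.outdir, "mine.tsv"), sep="\t",
                      float_format=_FLOAT_FMT)
        counts_by_class = result["class"].value_counts().to_dict()
        return {"files": ["mine.tsv"], "classes": counts_by_class}

    def stage_surface(self) -> dict:
        counts, sites, _ = self._load()
        cfg = self.config
        g = sites[cfg.gradient_column].to_numpy(float)
        dm = metrics.bray_curtis(counts)
        dm.to_csv(os.path.join(self.outdir, "bray_curtis.tsv"), sep="\t",
                  float_format=_FLOAT_FMT)
        pairs = surface.build_pair_dataset(g, dm)
        seed = stage_seed(cfg.seed, "surface")
        train, test = surface.split_train_test(pairs, cfg.train_frac, seed)
        gbt = surface.fit_gradient_boost(
            train, cfg.gbt_rounds, cfg.gbt_depth, cfg.gbt_learning_rate,
            cfg.gbt_reg_lambda, seed,
        )
        poly = surface.fit_polynomial(train, cfg.poly_degree)
        mesh = surface.predict_meshgrid(gbt, g, cfg.max_grid)
        mesh.to_frame().to_csv(os.path.join(self.outdir, "surface_gbt.tsv"),
                               sep="\t", float_format=_FLOAT_FMT)
        metrics_json = {}
        for name, model in (("gbt", gbt), ("polynomial", poly)):
            fit = surface.evaluate_model(model, test)
            metrics_json[name] = {
                "train_mse": fit.train_mse, "test_mse": fit.test_mse,
                "train_r2": fit.train_r2, "test_r2": fit.test_r2,
                "params": model.params,
            }
        metrics_json["surface_baseline_mean"] = mesh.baseline
        metrics_json["surface_step"] = mesh.step
        _write_json(os.path.join(self.outdir, "surface_metrics.json"), metrics_json)
        self._mesh = mesh
        return {
            "files": ["bray_curtis.tsv", "surface_gbt.tsv", "surface_metrics.json"],
            "gbt_test_r2": metrics_json["gbt"]["test_r2"],
            "polynomial_test_r2": metrics_json["polynomial"]["test_r2"],
        }

    def stage_thresholds(self) -> dict:
        cfg = self.config
        if not hasattr(self, "_mesh"):
            self.stage_surface()
        mesh = self._mesh
        profile = thresholds.turnover_profile(mesh, cfg.band_k)
        profile.to_frame().to_csv(
            os.path.join(self.outdir, "turnover_profile.tsv"), sep="\t",
            index=False, float_format=_FLOAT_FMT,
        )
        report = thresholds.detect_ridges_valleys(
            profile, mesh.baseline, cfg.min_prominence_frac,
            cfg.min_separation_frac, cfg.ridge_level_frac,
        )
        summary = thresholds.guardrail_summary(
            {cfg.gradient_column: report},
            {cfg.gradient_column: (float(mesh.axis[0]), float(mesh.axis[-1]))},
        )
        payload = {"report": report.to_dict(), "summary": summary}
        _write_json(os.path.join(self.outdir, "thresholds.json"), payload)
        return {
            "files": ["turnover_profile.tsv", "thresholds.json"],
            "n_ridges": len(report.ridges),
        }

    def stage_varpart(self) -> dict:
        counts, sites, spectra = self._load()
        cfg = self.config
        hel = metrics.hellinger_transform(counts)
        g = sites[cfg.gradient_column].to_numpy(float)
        sets: dict[str, np.ndarray] = {"gradient": g[:, None]}
        if spectra is not None:
            pca = metrics.cdom_pca_index(spectra)
            sets["cdom_pc1"] = pca.scores["pc1"].to_numpy()[:, None]
        if {"lon", "lat"} <= set(sites.columns):
            sets["space"] = sites[["lon", "lat"]].to_numpy(float)
        if len(sets) < 2:
            raise StageError("varpart needs >= 2 predictor sets "
                             "(gradient plus spectra or coordinates)")
        part = baselines.variance_partition(hel, sets)
        payload = {
            "fractions": {"+".join(k): v for k, v in part.fractions.items()},
            "residual": part.residual,
            "subset_adj_r2": {"+".join(k): v for k, v in part.subset_adj_r2.items()},
        }
        _write_json(os.path.join(self.outdir, "varpart.json"), payload)
        return {"files": ["varpart.json"], "residual": part.residual}

    # -- driver ------------------------------------------------------------
    def run(self, stages=("all",)) -> dict:
        if "all" in stages:
            stages = STAGES
        for name in stages:
            if name not in STAGES:
                raise ConfigError(f"unknown stage {name!r}")
        for name in stages:
            fn = getattr(self, f"stage_{name}")
            t0 = time.time()
            try:
                info = fn()
            except Exception as exc:
                marker = os.path.join(self.outdir, "FAILED")
                with open(marker, "w") as fh:
                    fh.write(f"{name}: {exc}\n")
                self._write_manifest()
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            info["seed"] = stage_seed(self.config.seed, name)
            info["seconds"] = round(time.time() - t0, 3)
            self.manifest["stages"][name] = info
            logger.info("stage %s done in %.2fs", name, info["seconds"])
        self._write_manifest()
        return self.manifest

    def _write_manifest(self) -> None:
        _write_json(os.path.join(self.outdir, "manifest.json"),
                    json.loads(json.dumps(self.manifest, default=str)))


def run_pipeline(config: RunConfig, stages=("all",)) -> dict:
    """Run the requested stages and return the manifest."""
    return PipelineRun(config).run(stages)
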