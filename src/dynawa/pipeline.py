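"""End-to-end pipeline: simulate -> preprocess -> split -> bands -> train ->
weigh -> evaluate -> curve.

One global seed fans out to per-stage seeds by stable hashing, so a fixed
seed makes the whole run reproducible while stages stay independently
re-runnable.  Band reduction is configurable: either GA band selection or a
plain wavelength stride (every ``wavelength_stride``-th column), the latter
being the default for desk-scale runs where the GA would dominate runtime.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import bands as bands_mod
from .ensemble import combine, count_curve, evaluate
from .learners import default_registry, fit_predict_all
from .preprocess import SGConfig, sg_smooth, trim_bands
from .split import split_two_to_one
from .synthetic import SimConfig, SpectraSet, simulate
from .weights import STRATEGIES, compute_weights

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "prepare_data"]

log = logging.getLogger("dynawa")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed below 2**31, stable in the stage name and global seed."""
    return (zlib.crc32(f"{stage}:{global_seed}".encode()) ^ global_seed) % (2 ** 31)


@dataclass
class RunConfig:
    seed: int = 1
    n_samples: int = 704
    fast: bool = True
    folds: int = 10
    strategies: tuple = STRATEGIES
    trim_low_nm: float = 400.0
    trim_high_nm: float = 2400.0
    use_ga_bands: bool = False
    band_fitness: str = "corr"
    ga_population: int = 30
    ga_generations: int = 20
    wavelength_stride: int = 25
    with_count_curve: bool = False
    count_curve_strategy: str = "sam"
    outdir: Path | None = None

    def __post_init__(self) -> None:
        if self.outdir is not None:
            self.outdir = Path(self.outdir)


def prepare_data(cfg: RunConfig) -> tuple[SpectraSet, SpectraSet]:
    """Simulate, preprocess, band-reduce and split; returns (cal, val)."""
    sim = simulate(SimConfig(n_samples=cfg.n_samples, seed=stage_seed(cfg.seed, "simulate")))
    log.info("simulated %d samples x %d wavelengths", sim.n_samples, sim.n_wavelengths)
    clean = sg_smooth(trim_bands(sim, cfg.trim_low_nm, cfg.trim_high_nm), SGConfig())
    if cfg.use_ga_bands:
        mask = bands_mod.ga_select_bands(
            clean,
            bands_mod.GABandConfig(
                population_size=cfg.ga_population,
                generations=cfg.ga_generations,
                fitness_name=cfg.band_fitness,
                seed=stage_seed(cfg.seed, "bands"),
            ),
        )
        reduced = SpectraSet(
            wavelengths=clean.wavelengths[mask.mask],
            reflectance=clean.reflectance[:, mask.mask],
            target=clean.target,
            sample_ids=list(clean.sample_ids),
        )
    else:
        idx = np.arange(0, clean.n_wavelengths, cfg.wavelength_stride)
        reduced = SpectraSet(
            wavelengths=clean.wavelengths[idx],
            reflectance=clean.reflectance[:, idx],
            target=clean.target,
            sample_ids=list(clean.sample_ids),
        )
    log.info("reduced to %d wavelength columns", reduced.n_wavelengths)
    split = split_two_to_one(reduced)
    return reduced.subset(split.calibration_idx), reduced.subset(split.validation_idx)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow and return (and optionally write) a report.

    The report maps each strategy to its weight vector and validation
    metrics; with ``with_count_curve`` it also carries the learner-count
    curve and detected plateau size.
    """
    cal, val = prepare_data(cfg)
    registry = default_registry()
    P_oof, P_val, trace = fit_predict_all(
        registry, cal, val, folds=cfg.folds, fast=cfg.fast,
        seed=stage_seed(cfg.seed, "train"),
    )
    log.info("trained %d learners (%d cal / %d val)", len(registry),
             cal.n_samples, val.n_samples)
    report: dict = {
        "seed": cfg.seed,
        "n_samples": cfg.n_samples,
        "n_calibration": cal.n_samples,
        "n_validation": val.n_samples,
        "n_learners": len(registry),
        "strategies": {},
    }
    for strat in cfg.strategies:
        wv = compute_weights(strat, P_oof, cal.target, trace=trace,
                             seed=stage_seed(cfg.seed, f"weights:{strat}"))
        metrics = evaluate(combine(P_val, wv), val.target)
        report["strategies"][strat] = {
            "weights": wv.as_dict(),
            "r2": metrics.r2,
            "rmse": metrics.rmse,
            "n": metrics.n,
        }
        log.info("strategy %-5s R2=%.4f RMSE=%.3f", strat, metrics.r2, metrics.rmse)
    if cfg.with_count_curve:
        curve = count_curve(P_oof, cal.target, P_val, val.target,
                            strategy=cfg.count_curve_strategy, trace=trace,
                            seed=stage_seed(cfg.seed, "curve"))
        report["count_curve"] = {
            "ranking": curve.ranking,
            "points": curve.points,
            "plateau_k": curve.plateau_k,
        }
    if cfg.outdir is not None:
        cfg.outdir.mkdir(parents=True, exist_ok=True)
        (cfg.outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
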