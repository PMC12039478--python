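"""Seeded generator of synthetic tracer studies with known ground truth.

Emulates the statistical structure the estimation pipeline assumes:

* a catalogue of regions with heavy-tailed (log-normal) neuron counts;
* a fixed subset of *true target* regions whose tracer density scales
  linearly with the injected volume (density = gain * volume * strength,
  with a per-region strength drawn once per study);
* a low uniform noise floor on *every* region, so that without a threshold
  all regions appear to receive projections and thresholding is
  consequential;
* a known ground-truth target:source ratio for recovery tests.

No spatial geometry or imaging statistics are modelled — only the features
the pipeline consumes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import (RegionCatalog, SourceNucleusParams, TracerExperiment,
                         write_experiments)

__all__ = [
    "GeneratorConfig",
    "generate_catalog",
    "generate_experiment",
    "generate_study",
    "ground_truth_ratio",
    "ground_truth_weighted_ratio",
    "true_target_ids",
    "write_study",
]

#: Injection volumes (mm^3) and confinement pattern mirroring the six
#: reference experiments: three spilling injections, three confined.
_DEFAULT_VOLUMES = (0.49, 0.54, 0.43, 0.23, 0.36, 0.17)
_DEFAULT_CONFINED = (False, False, False, True, True, True)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic tracer generator.

    Parameters
    ----------
    n_regions, n_true_targets
        Catalogue size (295, matching the non-overlapping gray-matter list
        used with the real data) and the number of regions that genuinely
        receive projections.
    count_median, count_dispersion
        Log-normal neuron-count distribution: median count per region and
        the standard deviation of log counts (heavy tail).
    source
        Source-nucleus volume and neuron count (defaults: mouse SNr).
    injection_volumes, confined
        One injection per experiment (mm^3) and whether it is confined to
        the source nucleus (proportion_in_source drawn near 1) or spills
        (drawn in [0.25, 0.45]).
    noise_floor
        Maximum spurious density added uniformly to every region; must stay
        below the weakest true-target density at the smallest injection.
    density_gain
        True-target density per mm^3 of injection (before the per-region
        strength factor).  The default 0.17 puts the density-weighted mean
        at the full nucleus volume near 0.085, so the lower-bound ratio is
        roughly 8.5% of the upper-bound ratio, as in the real data.
    strength_range
        Per-region strength multipliers, log-uniform over this range, so the
        arborization-weighted totals differ from the plain totals.
    target_ratio
        When set, true-target neuron counts are rescaled (integer rounding)
        so the ground-truth upper ratio equals this value exactly.
    target_weighted_ratio
        When set, the density gain is rescaled against the realized
        strengths so the expected lower-bound ratio at the source volume
        equals this value.
    seed
        Seeds the catalogue, target identities and strengths; experiment
        noise takes its own per-experiment seed.
    """

    n_regions: int = 295
    n_true_targets: int = 40
    count_median: float = 50_000.0
    count_dispersion: float = 1.5
    source: SourceNucleusParams = SourceNucleusParams()
    injection_volumes: tuple = _DEFAULT_VOLUMES
    confined: tuple = _DEFAULT_CONFINED
    noise_floor: float = 0.003
    density_gain: float = 0.17
    strength_range: tuple = (0.5, 1.0)
    target_ratio: float | None = None
    target_weighted_ratio: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_targets > self.n_regions:
            raise ValueError("n_true_targets cannot exceed n_regions")
        if not 0 <= self.noise_floor < 1:
            raise ValueError("noise_floor must lie in [0, 1)")
        if self.target_weighted_ratio is None:
            _check_noise_floor(self, self.density_gain)


def _check_noise_floor(config: "GeneratorConfig", gain: float) -> None:
    """Noise must stay below the weakest true-target signal so that some
    threshold cleanly separates signal from noise."""
    min_signal = gain * min(config.injection_volumes) * config.strength_range[0]
    if config.noise_floor >= min_signal:
        raise ValueError(
            "noise_floor must stay below the weakest true-target density "
            f"({min_signal:.4f}) at the smallest injection volume")


def _streams(config: GeneratorConfig):
    ss = np.random.SeedSequence(config.seed)
    counts_ss, targets_ss, noise_ss = ss.spawn(3)
    return counts_ss, targets_ss, noise_ss


def _true_target_structure(config: GeneratorConfig):
    """Target indices and per-region strengths, deterministic in config.seed."""
    _, targets_ss, _ = _streams(config)
    rng = np.random.default_rng(targets_ss)
    idx = rng.choice(config.n_regions, size=config.n_true_targets, replace=False)
    lo, hi = config.strength_range
    if lo <= 0 or hi < lo:
        raise ValueError("strength_range must be positive and ordered")
    strengths = np.exp(rng.uniform(np.log(lo), np.log(hi),
                                   size=config.n_true_targets))
    return np.sort(idx), strengths[np.argsort(idx)]


def true_target_ids(config: GeneratorConfig) -> list:
    """Region ids of the true targets for this configuration."""
    idx, _ = _true_target_structure(config)
    return [f"R{i:04d}" for i in idx]


def generate_catalog(config: GeneratorConfig) -> RegionCatalog:
    """Region catalogue with log-normal neuron counts, reproducible from seed.

    With ``target_ratio`` set, true-target counts are rescaled so their sum
    is ``target_ratio * source.neuron_count`` after integer rounding.
    """
    counts_ss, _, _ = _streams(config)
    rng = np.random.default_rng(counts_ss)
    counts = np.round(config.count_median
                      * np.exp(rng.normal(0.0, config.count_dispersion,
                                          size=config.n_regions))).astype(np.int64)
    counts = np.maximum(counts, 1)
    if config.target_ratio is not None:
        idx, _ = _true_target_structure(config)
        want = config.target_ratio * config.source.neuron_count
        have = counts[idx].sum()
        scaled = np.maximum(np.round(counts[idx] * want / have), 1).astype(np.int64)
        # absorb integer-rounding slack into the largest target
        scaled[np.argmax(scaled)] += int(round(want)) - scaled.sum()
        counts[idx] = scaled
    frame = pd.DataFrame({
        "region_id": [f"R{i:04d}" for i in range(config.n_regions)],
        "region_name": [f"synthetic region {i}" for i in range(config.n_regions)],
        "neuron_count": counts,
    })
    return RegionCatalog(frame)


def _effective_gain(catalog: RegionCatalog, config: GeneratorConfig) -> float:
    """Density gain after optional rescaling to a target weighted ratio."""
    if config.target_weighted_ratio is None:
        return config.density_gain
    idx, strengths = _true_target_structure(config)
    ids = [f"R{i:04d}" for i in idx]
    counts = catalog.neuron_counts(ids).to_numpy(dtype=float)
    weighted_sum = float((counts * strengths).sum())
    source = config.source
    return (config.target_weighted_ratio * source.neuron_count
            / (source.volume * weighted_sum))


def generate_experiment(catalog: RegionCatalog, config: GeneratorConfig,
                        injection_volume: float, seed: int,
                        confined: bool = True) -> TracerExperiment:
    """One synthetic injection experiment.

    True targets receive density ``min(0.999, gain * volume * strength)``;
    every region additionally receives uniform noise in (0, noise_floor],
    so that at theta = 0 the whole catalogue is "detected".  The signal
    component is deterministic given the config, so two experiments at
    volumes V and 2V have exactly doubled true-target signal; only the
    noise depends on ``seed``.
    """
    if injection_volume <= 0:
        raise ValueError("injection volume must be positive")
    idx, strengths = _true_target_structure(config)
    gain = _effective_gain(catalog, config)
    if config.target_weighted_ratio is not None:
        _check_noise_floor(config, gain)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, seed)))
    signal = np.zeros(config.n_regions)
    signal[idx] = gain * injection_volume * strengths
    if config.noise_floor > 0:
        # uniform on (0, noise_floor]: every region shows nonzero pixels
        noise = config.noise_floor * (1.0 - rng.random(config.n_regions))
    else:
        noise = np.zeros(config.n_regions)
    densities = np.minimum(0.999, signal + noise)
    if confined:
        proportion = rng.uniform(0.92, 0.98)
    else:
        proportion = rng.uniform(0.25, 0.45)
    region_ids = [f"R{i:04d}" for i in range(config.n_regions)]
    return TracerExperiment(
        experiment_id=f"synth-{seed:04d}",
        injection_volume=float(injection_volume),
        proportion_in_source=float(proportion),
        densities=pd.Series(densities, index=region_ids),
    )


def ground_truth_ratio(catalog: RegionCatalog, config: GeneratorConfig) -> float:
    """True upper-bound ratio: total true-target neurons per source neuron."""
    counts = catalog.neuron_counts(true_target_ids(config))
    return float(counts.sum()) / config.source.neuron_count


def ground_truth_weighted_ratio(catalog: RegionCatalog,
                                config: GeneratorConfig) -> float:
    """Expected lower-bound ratio at the full source volume.

    Density-weighted target neurons per source neuron when the injection
    fills the whole nucleus: gain * source_volume * sum(n_t * s_t) / S.
    """
    idx, strengths = _true_target_structure(config)
    ids = [f"R{i:04d}" for i in idx]
    counts = catalog.neuron_counts(ids).to_numpy(dtype=float)
    gain = _effective_gain(catalog, config)
    weighted = gain * config.source.volume * float((counts * strengths).sum())
    return weighted / config.source.neuron_count


def generate_study(config: GeneratorConfig):
    """Catalogue, one experiment per configured injection, and ground truth.

    Returns ``(catalog, experiments, truth)`` where ``truth`` holds the
    upper and weighted ground-truth ratios and the true-target ids.
    """
    catalog = generate_catalog(config)
    experiments = [
        generate_experiment(catalog, config, vol, seed=i, confined=conf)
        for i, (vol, conf) in enumerate(zip(config.injection_volumes,
                                            config.confined))
    ]
    truth = {
        "upper_ratio": ground_truth_ratio(catalog, config),
        "weighted_ratio": ground_truth_weighted_ratio(catalog, config),
        "true_targets": true_target_ids(config),
        "seed": config.seed,
    }
    return catalog, experiments, truth


def write_study(out_dir, config: GeneratorConfig) -> dict:
    """Write the three pipeline input tables plus a ground-truth JSON.

    Emits ``catalog.tsv``, ``experiments.tsv``, ``densities.tsv`` and
    ``ground_truth.json`` under ``out_dir``; returns the truth record.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog, experiments, truth = generate_study(config)
    catalog.to_csv(out / "catalog.tsv")
    write_experiments(experiments, out / "experiments.tsv", out / "densities.tsv")
    record = dict(truth)
    record["config"] = {k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                        for k, v in dataclasses.asdict(config).items()}
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(record, fh, indent=2)
    return record
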