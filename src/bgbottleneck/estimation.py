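"""Anatomical bottleneck estimation from anterograde tracer experiments.

Quantifies the expansion from a small inhibitory source nucleus (the
substantia nigra pars reticulata, SNr, in the reference dataset) to its
target regions, using pre-exported tables from tracer injection
experiments:

1. intersect each experiment's per-region fluorescence densities with a
   catalogue of non-overlapping gray matter regions;
2. reject regions whose density falls below a noise threshold theta;
3. sum neuron counts over retained regions (upper bound on contacted
   neurons) and density-weighted counts (lower bound, approximating axonal
   arborization);
4. fit a linear model of total target neurons against injected volume and
   extrapolate to the full source-nucleus volume;
5. sweep theta and detect the asymptotic target:source ratio.

An alternative per-experiment route, for injections confined to the
source, scales the source neuron count by the injected fraction of the
nucleus volume (S-hat) instead of extrapolating.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegionCatalog",
    "TracerExperiment",
    "SourceNucleusParams",
    "ScalingFit",
    "ThresholdSweepResult",
    "DEFAULT_THETA_GRID",
    "ALLEN_SNR_TABLE",
    "filter_targets",
    "total_target_neurons",
    "arborization_weighted_neurons",
    "fit_scaling_model",
    "extrapolate_to_source",
    "ratio_sweep",
    "detect_asymptote",
    "per_experiment_ratio",
    "proportion_of_source_injected",
    "striatal_compression_ratio",
    "read_catalog",
    "read_experiments",
]

#: Threshold grid used throughout: 0 to 0.05 in steps of 0.005.
DEFAULT_THETA_GRID = tuple(np.round(np.arange(0.0, 0.0501, 0.005), 4))

#: Injection metadata for the six SNr tracer experiments of the reference
#: dataset (Allen Mouse Brain Connectivity Atlas): injected volume (mm^3)
#: and the proportion of the injection inside the SNr.
ALLEN_SNR_TABLE = pd.DataFrame(
    {
        "experiment_id": ["478096249", "158914182", "478097069",
                          "100141993", "299895444", "175263063"],
        "injection_volume": [0.49, 0.54, 0.43, 0.23, 0.36, 0.17],
        "proportion_in_source": [0.41, 0.29, 0.32, 0.95, 0.94, 0.96],
    }
).set_index("experiment_id")


@dataclass(frozen=True)
class SourceNucleusParams:
    """Volume (mm^3) and neuron count of the source nucleus.

    Defaults are the mouse SNr: 0.69 mm^3 and ~12,000 neurons.
    """

    volume: float = 0.69
    neuron_count: int = 12_000

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.neuron_count <= 0:
            raise ValueError("source nucleus volume and neuron count must be positive")


class RegionCatalog:
    """Catalogue of non-overlapping brain regions with neuron counts."""

    def __init__(self, frame: pd.DataFrame):
        required = {"region_id", "region_name", "neuron_count"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"catalogue missing columns: {sorted(missing)}")
        if frame["region_id"].duplicated().any():
            raise ValueError("catalogue region ids must be unique")
        if (frame["neuron_count"] < 0).any():
            raise ValueError("neuron counts must be nonnegative")
        self.frame = frame.reset_index(drop=True)
        self._counts = frame.set_index("region_id")["neuron_count"]

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, region_id) -> bool:
        return region_id in self._counts.index

    @property
    def region_ids(self) -> pd.Index:
        return self._counts.index

    def neuron_count(self, region_id) -> int:
        try:
            return int(self._counts.loc[region_id])
        except KeyError:
            raise KeyError(f"region {region_id!r} not in catalogue") from None

    def neuron_counts(self, region_ids: Sequence) -> pd.Series:
        unknown = [r for r in region_ids if r not in self._counts.index]
        if unknown:
            raise KeyError(f"regions not in catalogue: {unknown[:5]}")
        return self._counts.loc[list(region_ids)]

    def total_neurons(self) -> int:
        return int(self._counts.sum())

    def to_csv(self, path, sep: str = "\t") -> None:
        self.frame.to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path, sep: str = "\t") -> "RegionCatalog":
        return cls(pd.read_csv(path, sep=sep))


@dataclass
class TracerExperiment:
    """One anterograde tracer injection with per-region tracer densities.

    ``densities`` maps region id to the fraction d_t in [0, 1) of that
    region's volume occupied by fluorescent tracer; it serves both as the
    noise-filter statistic and as the arborization weight.
    """

    experiment_id: str
    injection_volume: float
    proportion_in_source: float
    densities: pd.Series

    def __post_init__(self) -> None:
        if self.injection_volume <= 0:
            raise ValueError("injection volume must be positive")
        if not 0 <= self.proportion_in_source <= 1:
            raise ValueError("proportion_in_source must lie in [0, 1]")
        d = pd.Series(self.densities, dtype=float)
        if ((d < 0) | (d >= 1)).any():
            raise ValueError("densities must lie in [0, 1)")
        self.densities = d


def filter_targets(experiment: TracerExperiment, catalog: RegionCatalog,
                   theta: float) -> list:
    """Regions whose tracer density reaches the threshold ``theta``.

    Retains regions with d_t >= theta, intersected with the catalogue
    (regions outside the non-overlapping list are ignored).  The >=
    comparison means theta = 0 retains every region with any tracer.
    """
    if not 0 <= theta < 1:
        raise ValueError("theta must lie in [0, 1)")
    d = experiment.densities
    retained = d.index[d >= theta]
    return [r for r in retained if r in catalog]


def total_target_neurons(retained: Iterable, catalog: RegionCatalog) -> int:
    """Sum of neuron counts over retained regions: the upper bound."""
    retained = list(retained)
    if not retained:
        return 0
    return int(catalog.neuron_counts(retained).sum())


def arborization_weighted_neurons(retained: Iterable, densities: pd.Series,
                                  catalog: RegionCatalog) -> float:
    """Density-weighted neuron sum over retained regions: the lower bound.

    Weights each region's neuron count by its tracer density d_t,
    approximating the fraction of the region reached by the arborizing
    axons; always <= the unweighted total since d_t < 1.
    """
    retained = list(retained)
    if not retained:
        return 0.0
    counts = catalog.neuron_counts(retained)
    return float((counts * densities.loc[retained]).sum())


class ScalingFit:
    """Linear model of target-neuron totals against injected volume.

    Thin wrapper over an ordinary (or weighted) least-squares fit exposing
    the slope, intercept, and mean-response / prediction intervals at an
    arbitrary volume.
    """

    def __init__(self, results, weighted: bool):
        self._results = results
        self.weighted = weighted
        params = np.asarray(results.params)
        self.intercept = float(params[0])
        self.slope = float(params[1])

    @property
    def rsquared(self) -> float:
        return float(self._results.rsquared)

    def predict(self, volume: float, interval: str = "mean",
                alpha: float = 0.05) -> tuple[float, float, float]:
        """Predicted total at ``volume`` with a 95% interval (mean, lo, hi).

        ``interval='mean'`` gives the confidence interval of the mean
        response (as plotted around a fit line); ``'prediction'`` gives the
        wider interval for a new observation.
        """
        X = np.array([[1.0, float(volume)]])
        pred = self._results.get_prediction(X)
        frame = pred.summary_frame(alpha=alpha)
        mean = float(frame["mean"].iloc[0])
        if interval == "mean":
            lo, hi = frame["mean_ci_lower"].iloc[0], frame["mean_ci_upper"].iloc[0]
        elif interval == "prediction":
            lo, hi = frame["obs_ci_lower"].iloc[0], frame["obs_ci_upper"].iloc[0]
        else:
            raise ValueError("interval must be 'mean' or 'prediction'")
        return mean, float(lo), float(hi)


def fit_scaling_model(points: Sequence[tuple[float, float]],
                      weights: Sequence[float] | None = None) -> ScalingFit:
    """Fit total target neurons vs injection volume by (weighted) least squares.

    ``points`` are (injection_volume, neuron_total) pairs; ``weights``, when
    given, weight each point (e.g. by the proportion of the source filled).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (volume, total) points")
    volumes, totals = pts[:, 0], pts[:, 1]
    if np.unique(volumes).size < 2:
        raise ValueError("degenerate fit: all injection volumes equal")
    X = sm.add_constant(volumes)
    if weights is None:
        results = sm.OLS(totals, X).fit()
        return ScalingFit(results, weighted=False)
    w = np.asarray(weights, dtype=float)
    if w.size != volumes.size:
        raise ValueError("one weight per point required")
    results = sm.WLS(totals, X, weights=w).fit()
    return ScalingFit(results, weighted=True)


def extrapolate_to_source(model: ScalingFit, source: SourceNucleusParams,
                          interval: str = "mean") -> tuple[float, float, float]:
    """Extrapolate the fitted scaling to the full source-nucleus volume."""
    return model.predict(source.volume, interval=interval)


def detect_asymptote(ratios: Sequence[float]) -> float | None:
    """Stable value of a ratio sequence ordered by increasing threshold.

    Scans for the first window of three consecutive estimates whose
    successive absolute changes are both strictly less than 1, and returns
    the final element of that window; ``None`` when no window qualifies.
    """
    vals = [float(r) for r in ratios]
    if len(vals) < 3:
        warnings.warn("fewer than 3 estimates; asymptote undefined", stacklevel=2)
        return None
    for i in range(len(vals) - 2):
        if abs(vals[i + 1] - vals[i]) < 1 and abs(vals[i + 2] - vals[i + 1]) < 1:
            return vals[i + 2]
    return None


@dataclass
class ThresholdSweepResult:
    """Per-threshold target:source ratios and their detected asymptotes."""

    thresholds: np.ndarray
    upper_ratios: np.ndarray
    lower_ratios: np.ndarray
    asymptote_upper: float | None
    asymptote_lower: float | None
    #: retained-region counts, shape (n_thresholds, n_experiments)
    retained_counts: np.ndarray = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "theta": self.thresholds,
            "upper_ratio": self.upper_ratios,
            "lower_ratio": self.lower_ratios,
        })

    def to_json(self, path) -> None:
        payload = {
            "thresholds": list(map(float, self.thresholds)),
            "upper_ratios": list(map(float, self.upper_ratios)),
            "lower_ratios": list(map(float, self.lower_ratios)),
            "asymptote_upper": self.asymptote_upper,
            "asymptote_lower": self.asymptote_lower,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _aggregate(experiment: TracerExperiment, catalog: RegionCatalog,
               theta: float) -> tuple[int, float, int]:
    retained = filter_targets(experiment, catalog, theta)
    upper = total_target_neurons(retained, catalog)
    lower = arborization_weighted_neurons(retained, experiment.densities, catalog)
    return upper, lower, len(retained)


def ratio_sweep(experiments: Sequence[TracerExperiment], catalog: RegionCatalog,
                source: SourceNucleusParams,
                thetas: Sequence[float] = DEFAULT_THETA_GRID,
                weighted: bool = False) -> ThresholdSweepResult:
    """Sweep the density threshold and compute both ratio bounds per theta.

    At each theta: filter targets, aggregate the upper (neuron-count) and
    lower (density-weighted) totals per experiment, fit each set of totals
    against injection volume, extrapolate to the source volume, and divide
    by the source neuron count.  ``weighted=True`` weights the fits by each
    experiment's proportion of the injection inside the source.
    """
    thetas = np.asarray(sorted(thetas), dtype=float)
    weights = ([e.proportion_in_source for e in experiments] if weighted else None)
    upper_ratios, lower_ratios, counts = [], [], []
    for theta in thetas:
        try:
            per_exp = [_aggregate(e, catalog, theta) for e in experiments]
            volumes = [e.injection_volume for e in experiments]
            upper_fit = fit_scaling_model(list(zip(volumes, [u for u, _, _ in per_exp])),
                                          weights)
            lower_fit = fit_scaling_model(list(zip(volumes, [l for _, l, _ in per_exp])),
                                          weights)
            upper_pred, _, _ = extrapolate_to_source(upper_fit, source)
            lower_pred, _, _ = extrapolate_to_source(lower_fit, source)
        except Exception as exc:
            raise RuntimeError(f"ratio sweep failed at theta={theta}") from exc
        upper_ratios.append(upper_pred / source.neuron_count)
        lower_ratios.append(lower_pred / source.neuron_count)
        counts.append([c for _, _, c in per_exp])
    upper_ratios = np.asarray(upper_ratios)
    lower_ratios = np.asarray(lower_ratios)
    return ThresholdSweepResult(
        thresholds=thetas,
        upper_ratios=upper_ratios,
        lower_ratios=lower_ratios,
        asymptote_upper=detect_asymptote(upper_ratios),
        asymptote_lower=detect_asymptote(lower_ratios),
        retained_counts=np.asarray(counts),
    )


def per_experiment_ratio(experiment: TracerExperiment, catalog: RegionCatalog,
                         source: SourceNucleusParams, theta: float,
                         use_raw_volume: bool = False) -> tuple[float, float]:
    """Target:source ratios for a single injection via the S-hat route.

    S-hat estimates the number of source neurons covered by the injection:
    ``source.neuron_count * effective_volume / source.volume``.  The
    effective volume defaults to ``injection_volume * proportion_in_source``
    (the part actually inside the nucleus); ``use_raw_volume=True`` uses the
    raw injected volume instead.  Intended for injections confined to the
    source (proportion_in_source > 0.9).

    Returns (upper_ratio, lower_ratio).
    """
    volume = experiment.injection_volume
    if not use_raw_volume:
        volume = volume * experiment.proportion_in_source
    s_hat = source.neuron_count * volume / source.volume
    if s_hat == 0:
        raise ZeroDivisionError("S-hat is zero: empty effective injection")
    upper, lower, _ = _aggregate(experiment, catalog, theta)
    return upper / s_hat, lower / s_hat


def proportion_of_source_injected(injection_volume: float,
                                  proportion_in_source: float,
                                  source_volume: float = 0.69) -> float:
    """Fraction of the source nucleus filled by an injection, to 2 decimals.

    ``injection_volume * proportion_in_source / source_volume``, rounded
    half-up to two decimals for comparison with printed injection tables.
    Values above 1 are capped with a warning.
    """
    if injection_volume <= 0 or source_volume <= 0:
        raise ValueError("volumes must be positive")
    frac = injection_volume * proportion_in_source / source_volume
    if frac > 1:
        warnings.warn(f"injection covers {frac:.2f} > 1 of the source; capping at 1",
                      stacklevel=2)
        frac = 1.0
    return float(Decimal(repr(frac)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def striatal_compression_ratio(n_projection_neurons: int = 400_000,
                               direct_pathway_fraction: float = 0.5,
                               n_source_neurons: int = 12_000) -> float:
    """Convergence of striatal projection neurons onto the output nucleus.

    With ~400,000 mouse striatal projection neurons, half of them
    direct-pathway (D1-expressing, hence projecting to the SNr), and
    ~12,000 SNr neurons, the compression is about 16 striatal neurons per
    output neuron.
    """
    return direct_pathway_fraction * n_projection_neurons / n_source_neurons


# -- table I/O ---------------------------------------------------------------

def read_catalog(path, sep: str = "\t") -> RegionCatalog:
    """Read a region catalogue table (region_id, region_name, neuron_count)."""
    return RegionCatalog.from_csv(path, sep=sep)


def read_experiments(experiments_path, densities_path,
                     sep: str = "\t") -> list[TracerExperiment]:
    """Read experiment metadata and long-format density tables.

    ``experiments``: experiment_id, injection_volume_mm3, proportion_in_source.
    ``densities``: experiment_id, region_id, density.
    """
    meta = pd.read_csv(experiments_path, sep=sep, dtype={"experiment_id": str})
    dens = pd.read_csv(densities_path, sep=sep,
                       dtype={"experiment_id": str})
    experiments = []
    for _, row in meta.iterrows():
        block = dens[dens["experiment_id"] == row["experiment_id"]]
        experiments.append(TracerExperiment(
            experiment_id=row["experiment_id"],
            injection_volume=float(row["injection_volume_mm3"]),
            proportion_in_source=float(row["proportion_in_source"]),
            densities=block.set_index("region_id")["density"],
        ))
    return experiments


def write_experiments(experiments: Sequence[TracerExperiment],
                      experiments_path, densities_path, sep: str = "\t") -> None:
    """Write the experiment metadata and density tables consumed by loaders."""
    meta = pd.DataFrame({
        "experiment_id": [e.experiment_id for e in experiments],
        "injection_volume_mm3": [e.injection_volume for e in experiments],
        "proportion_in_source": [e.proportion_in_source for e in experiments],
    })
    meta.to_csv(experiments_path, sep=sep, index=False)
    blocks = []
    for e in experiments:
        block = e.densities.rename("density").rename_axis("region_id").reset_index()
        block.insert(0, "experiment_id", e.experiment_id)
        blocks.append(block)
    pd.concat(blocks, ignore_index=True).to_csv(densities_path, sep=sep, index=False)
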