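"""Stabilized supralinear network (SSN) model of a cortical circuit.

Demonstrates how a handful of basal ganglia output neurons, acting as
dynamic weights on overlapping thalamic basis functions, can redirect the
population trajectory of a much larger cortical network.

The network obeys

    tau dx/dt = -x + W r(x) + I(t),      r(x_i) = k * max(0, x_i)**eta,

with tau = 20 ms, k = 0.1, eta = 2, and a random N x N connectivity W
whose columns are wholly excitatory or wholly inhibitory.  A step of input
is applied in a fixed window; the thalamic portion of that step is
T = T_b - |D| a, i.e. baseline thalamic drive minus basal-ganglia
inhibition through the basis matrix D.  Varying only the output vector
``a`` while freezing every other input reshapes the low-dimensional
trajectory of the cortical response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr
from sklearn.decomposition import PCA

from .basis import BasisMatrix

__all__ = [
    "ConnectivityConfig",
    "SSNNetwork",
    "InputProtocol",
    "Trajectory",
    "LowDimTrajectory",
    "InstabilityError",
    "build_connectivity",
    "ssn_rate",
    "thalamic_input",
    "simulate",
    "pca_trajectory",
    "output_trajectory_correlation",
]


class InstabilityError(RuntimeError):
    """Numerical divergence of the forward-Euler integration."""


@dataclass(frozen=True)
class ConnectivityConfig:
    """Random E/I connectivity: Bernoulli(p) adjacency, spectral radius R.

    ``ei_weight_ratio`` (gamma) scales inhibitory weights relative to
    excitatory ones; ``stability_optimize`` is a hook for eigenvalue
    minimization of W (not implemented; random W suffices here).
    """

    connection_probability: float = 0.1
    ei_weight_ratio: float = 3.0
    spectral_radius: float = 10.0
    stability_optimize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.connection_probability < 1:
            raise ValueError("connection probability must lie in (0, 1)")
        if self.ei_weight_ratio < 0 or self.spectral_radius <= 0:
            raise ValueError("gamma must be >= 0 and R > 0")


@dataclass
class SSNNetwork:
    """An SSN with fixed connectivity and rate nonlinearity parameters."""

    weights: np.ndarray
    time_constant: float = 20.0   # ms
    rate_gain: float = 0.1        # k
    rate_exponent: float = 2.0    # eta
    excitatory_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("connectivity must be square")
        # Dale's law: each column wholly excitatory or wholly inhibitory
        if not np.all((W >= 0).all(axis=0) | (W <= 0).all(axis=0)):
            raise ValueError("each column must be all-nonnegative or all-nonpositive")
        self.weights = W

    @property
    def n_units(self) -> int:
        return self.weights.shape[0]


def build_connectivity(config: ConnectivityConfig, n_units: int = 200,
                       excitatory_fraction: float = 0.8) -> SSNNetwork:
    """Sample a random E/I connectivity matrix with target spectral radius.

    Units connect with probability p; a random subset of columns (fraction
    ``excitatory_fraction``) is excitatory with weight ``w0/sqrt(N)``, the
    rest inhibitory with ``-gamma*w0/sqrt(N)``.  The scale

        w0 = R / sqrt( p (1-p) (f + (1-f) gamma^2) )

    (f the excitatory fraction) sets the expected bulk spectral radius to
    R by the circular law; at f = 0.5 this reduces to the familiar
    ``R / sqrt(p(1-p)(1+gamma^2)/2)``.  Realized radii scatter within
    about 15% of R at N = 200.
    """
    if config.stability_optimize:
        raise NotImplementedError(
            "eigenvalue-minimizing stability optimization is a hook only; "
            "random connectivity gives qualitatively identical dynamics")
    if not 0 < excitatory_fraction <= 1:
        raise ValueError("excitatory_fraction must lie in (0, 1]")
    p = config.connection_probability
    gamma = config.ei_weight_ratio
    f = excitatory_fraction
    w0 = config.spectral_radius / np.sqrt(p * (1 - p) * (f + (1 - f) * gamma ** 2))

    rng = np.random.default_rng(config.seed)
    adjacency = rng.random((n_units, n_units)) < p
    n_exc = int(round(f * n_units))
    exc_mask = np.zeros(n_units, dtype=bool)
    exc_mask[rng.permutation(n_units)[:n_exc]] = True
    col_weight = np.where(exc_mask, w0, -gamma * w0) / np.sqrt(n_units)
    W = adjacency * col_weight[np.newaxis, :]
    return SSNNetwork(weights=W, excitatory_mask=exc_mask)


def ssn_rate(x, k: float = 0.1, eta: float = 2.0):
    """Rectified power-law transfer: r = k * max(0, x)**eta."""
    return k * np.maximum(0.0, np.asarray(x, dtype=float)) ** eta


def thalamic_input(a: np.ndarray, D: BasisMatrix, baseline: float = 1.0,
                   clip: bool = False) -> np.ndarray:
    """Thalamic drive under basal ganglia inhibition: T = T_b - |D| a.

    ``D`` follows the inhibitory convention (entries <= 0), so this is
    computed as ``T_b + D a`` — identical to subtracting the
    magnitude-form basis matrix.  With ``clip=True`` the drive is floored
    at zero (a silenced thalamic unit cannot be driven negative).
    """
    a = np.asarray(a, dtype=float).ravel()
    if a.size != D.b:
        raise ValueError(f"output vector has length {a.size}, expected {D.b}")
    if np.any(a < 0):
        raise ValueError("output activity must be nonnegative")
    T = baseline + D.weights @ a
    return np.maximum(T, 0.0) if clip else T


@dataclass
class InputProtocol:
    """The stepped input protocol: background, then a frozen step window.

    Background input 0.1 is applied to every unit outside the step window
    [1000, 2000] ms.  Inside it, a fixed random 10% of units receive the
    thalamic drive ``T_b - |D| a`` and the remainder receive individual
    step values drawn once from [0, 1] and then frozen, so that across
    simulations only the basal ganglia output vector ``a`` varies.
    """

    basis: BasisMatrix
    thalamic_indices: np.ndarray
    cortical_step: np.ndarray
    background: float = 0.1
    step_window: tuple = (1000.0, 2000.0)
    total_duration: float = 3000.0
    time_step: float = 0.1          # ms
    thalamic_baseline: float = 1.0
    bg_output_range: tuple = (0.0, 0.4)

    @classmethod
    def sample(cls, basis: BasisMatrix, n_units: int, seed: int = 0,
               thalamic_fraction: float = 0.1, **kwargs) -> "InputProtocol":
        """Draw the frozen parts of the protocol: which units are thalamic,
        and the cortical step values."""
        rng = np.random.default_rng(seed)
        n_thal = int(round(thalamic_fraction * n_units))
        if n_thal != basis.n:
            raise ValueError(
                f"basis has {basis.n} thalamic targets but protocol expects {n_thal}")
        thalamic = rng.permutation(n_units)[:n_thal]
        cortical = rng.uniform(0.0, 1.0, size=n_units - n_thal)
        return cls(basis=basis, thalamic_indices=np.sort(thalamic),
                   cortical_step=cortical, **kwargs)

    def sample_output(self, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.bg_output_range
        return rng.uniform(lo, hi, size=self.basis.b)

    def input_matrix(self, n_units: int, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(background vector, step vector) of per-unit input levels."""
        bg = np.full(n_units, self.background)
        step = np.empty(n_units)
        cortical_mask = np.ones(n_units, dtype=bool)
        cortical_mask[self.thalamic_indices] = False
        step[cortical_mask] = self.cortical_step
        step[self.thalamic_indices] = thalamic_input(
            a, self.basis, self.thalamic_baseline)
        return bg, step


@dataclass
class Trajectory:
    """Recorded rate time series of one simulation."""

    times: np.ndarray            # ms
    rates: np.ndarray            # (T_rec, N), nonnegative
    output_vector: np.ndarray    # the a that produced it
    step_window: tuple

    def window_mask(self) -> np.ndarray:
        lo, hi = self.step_window
        return (self.times >= lo) & (self.times <= hi)


def simulate(network: SSNNetwork, protocol: InputProtocol,
             a: np.ndarray | None = None, seed: int | None = None,
             record_every: int = 10, x_ceiling: float = 1e6) -> Trajectory:
    """Forward-Euler integration of the SSN under the stepped protocol.

    If ``a`` is not given it is drawn uniformly from the protocol's output
    range using ``seed`` — the only part resampled between simulations.
    Rates are recorded every ``record_every`` Euler steps (1 ms at the
    default 0.1 ms time step).  Any potential exceeding ``x_ceiling`` in
    magnitude aborts with :class:`InstabilityError` naming the seed.
    """
    if a is None:
        a = protocol.sample_output(np.random.default_rng(seed))
    a = np.asarray(a, dtype=float).ravel()
    N = network.n_units
    bg, step = protocol.input_matrix(N, a)
    dt, tau = protocol.time_step, network.time_constant
    n_steps = int(round(protocol.total_duration / dt))
    lo, hi = protocol.step_window

    x = np.zeros(N)
    n_rec = n_steps // record_every + 1
    rates = np.empty((n_rec, N))
    times = np.empty(n_rec)
    W = network.weights
    k, eta = network.rate_gain, network.rate_exponent
    rec = 0
    for step_i in range(n_steps + 1):
        t = step_i * dt
        if step_i % record_every == 0 and rec < n_rec:
            rates[rec] = ssn_rate(x, k, eta)
            times[rec] = t
            rec += 1
        if step_i == n_steps:
            break
        I = step if lo <= t <= hi else bg
        r = ssn_rate(x, k, eta)
        x = x + (dt / tau) * (-x + W @ r + I)
        if np.max(np.abs(x)) > x_ceiling:
            raise InstabilityError(
                f"potential exceeded {x_ceiling:g} at t={t:.1f} ms "
                f"(seed={seed}, |a|={np.linalg.norm(a):.3f})")
    return Trajectory(times=times[:rec], rates=rates[:rec],
                      output_vector=a, step_window=protocol.step_window)


@dataclass
class LowDimTrajectory:
    """Principal-component projection of a trajectory."""

    times: np.ndarray
    coords: np.ndarray                 # (T_rec, n_components)
    explained_variance_ratio: np.ndarray
    baseline_point: np.ndarray
    step_window: tuple

    def distance_from_baseline(self) -> np.ndarray:
        return np.linalg.norm(self.coords - self.baseline_point, axis=1)


def pca_trajectory(trajectory: Trajectory, n_components: int = 3,
                   baseline_span: float = 200.0) -> LowDimTrajectory:
    """Project the rate time series onto its leading principal components.

    The baseline point is the mean projection over the final
    ``baseline_span`` ms before the step window begins.  Constant activity
    triggers a zero-variance warning and a zero projection.
    """
    rates = trajectory.rates
    if n_components > rates.shape[1]:
        raise ValueError("n_components cannot exceed the number of units")
    if np.allclose(rates.var(axis=0), 0.0):
        warnings.warn("activity is constant: zero-variance projection",
                      stacklevel=2)
        coords = np.zeros((rates.shape[0], n_components))
        evr = np.zeros(n_components)
    else:
        pca = PCA(n_components=n_components)
        coords = pca.fit_transform(rates)
        evr = pca.explained_variance_ratio_
    lo = trajectory.step_window[0]
    base_mask = (trajectory.times >= lo - baseline_span) & (trajectory.times < lo)
    if not base_mask.any():
        base_mask = trajectory.times < lo
    baseline = coords[base_mask].mean(axis=0)
    return LowDimTrajectory(times=trajectory.times, coords=coords,
                            explained_variance_ratio=evr,
                            baseline_point=baseline,
                            step_window=trajectory.step_window)


def trajectory_distances(trajectories: list[Trajectory],
                         n_components: int = 3) -> np.ndarray:
    """Condensed pairwise distances between trajectories.

    Projects all trajectories into a common principal-component space
    (fit on the pooled rates) and measures, for each pair, the mean
    pointwise Euclidean distance over the step window.
    """
    pooled = np.vstack([t.rates for t in trajectories])
    pca = PCA(n_components=n_components)
    pca.fit(pooled)
    projs = [pca.transform(t.rates) for t in trajectories]
    masks = [t.window_mask() for t in trajectories]
    m = len(trajectories)
    out = []
    for i in range(m):
        for j in range(i + 1, m):
            n = min(masks[i].sum(), masks[j].sum())
            pi = projs[i][masks[i]][:n]
            pj = projs[j][masks[j]][:n]
            out.append(np.linalg.norm(pi - pj, axis=1).mean())
    return np.asarray(out)


def output_trajectory_correlation(bg_outputs: list[np.ndarray],
                                  trajectories: list[Trajectory],
                                  n_components: int = 3) -> float:
    """Spearman rank correlation between output and trajectory distances.

    Compares pairwise Euclidean distances among basal ganglia output
    vectors with pairwise trajectory distances (mean pointwise distance in
    the top principal components over the step window).  A positive
    correlation means more distinct outputs push cortex onto more distinct
    trajectories.
    """
    if len(bg_outputs) != len(trajectories):
        raise ValueError("need one trajectory per output vector")
    if len(bg_outputs) < 3:
        raise ValueError("rank correlation needs at least 3 output vectors")
    d_out = pdist(np.vstack([np.ravel(a) for a in bg_outputs]))
    d_traj = trajectory_distances(trajectories, n_components)
    if np.allclose(d_traj, d_traj[0]):
        warnings.warn("all trajectory distances tied; correlation undefined",
                      stacklevel=2)
        return float("nan")
    rho, _ = spearmanr(d_out, d_traj)
    return float(rho)
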