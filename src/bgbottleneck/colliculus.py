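"""Superior colliculus build-up layer under a spanning basal ganglia code.

The build-up (intermediate) layer is an N x N grid of leaky units

    tau ds/dt = -s + u(t) + D a,       r = max(0, s),

with tau = 10 ms.  Saccade targets arrive as nonnegative drive ``u``;
2N basal ganglia output neurons inhibit the grid through a *spanning*
basis matrix D whose entries are -1 or 0, each output neuron covering one
entire row or one entire column.  A coordinate (i, j) is then selected by
pausing just two neurons — row neuron i and column neuron j — so the
number of selectable coordinates grows as the product of the two axis
group sizes rather than linearly in the neuron count.

Four scenarios reproduce the selection logic: tonic inhibition suppresses
all build-up; paused row+column neurons select one target; a competitor
sharing the paused column leaks through; and boosting the competitor's
row neuron above tonic restores single-target selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .basis import BasisMatrix

__all__ = [
    "GridModel",
    "GridTrajectory",
    "ScenarioReport",
    "SCENARIOS",
    "build_spanning_basis",
    "fixed_point",
    "simulate_grid",
    "count_hills",
    "run_scenario",
    "selectable_coordinates",
]

SCENARIOS = ("tonic", "pause", "competing", "competing_corrected")

#: Absolute activity threshold (drive units) above which a unit counts
#: toward a hill of saccadic activity.
HILL_THRESHOLD = 0.05


@dataclass(frozen=True)
class GridModel:
    """The build-up layer grid: side length, time constant (ms), Euler step."""

    side: int = 20
    time_constant: float = 10.0
    time_step: float = 0.1

    def __post_init__(self) -> None:
        if self.side < 2:
            raise ValueError("grid side must be at least 2")
        if self.time_constant <= 0 or self.time_step <= 0:
            raise ValueError("time constant and step must be positive")

    @property
    def n_units(self) -> int:
        return self.side * self.side


def build_spanning_basis(side: int) -> BasisMatrix:
    """Spanning-code basis: one output neuron per grid row and per column.

    Returns an (side^2) x (2*side) matrix with entries in {-1, 0}: grid
    cell (i, j) — flattened row-major to index i*side + j — receives -1
    from row neuron i (column i of the matrix) and from column neuron j
    (matrix column side + j).  Each matrix column has exactly ``side``
    entries of -1 and each grid cell exactly two inhibitory inputs.
    """
    if side < 2:
        raise ValueError("spanning code needs a grid side of at least 2")
    n = side * side
    W = np.zeros((n, 2 * side))
    rows, cols = np.divmod(np.arange(n), side)
    W[np.arange(n), rows] = -1.0
    W[np.arange(n), side + cols] = -1.0
    return BasisMatrix(W, topology="grid_spanning", meta={"side": side})


def fixed_point(u: np.ndarray, D: BasisMatrix, a: np.ndarray) -> np.ndarray:
    """Analytic steady state of the grid dynamics: s* = u + D a."""
    return np.asarray(u, dtype=float).ravel() + D.weights @ np.asarray(a, float)


@dataclass
class GridTrajectory:
    """State time series of one grid simulation."""

    times: np.ndarray
    states: np.ndarray     # (T_rec, side*side)
    side: int

    @property
    def rates(self) -> np.ndarray:
        """Rectified output r = max(0, s)."""
        return np.maximum(0.0, self.states)

    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def final_rate_grid(self) -> np.ndarray:
        return self.rates[-1].reshape(self.side, self.side)


def simulate_grid(model: GridModel, u: np.ndarray, a: np.ndarray,
                  duration: float = 200.0, record_every: int = 10,
                  s_ceiling: float = 1e6) -> GridTrajectory:
    """Forward-Euler integration of the build-up layer from rest.

    ``u`` is the (flattened or 2-D) nonnegative target drive; ``a`` the
    2N-vector of nonnegative output rates.  The default 200 ms run is 20
    time constants, ample for the state to settle within 1% of the fixed
    point s* = u + D a.
    """
    u = np.asarray(u, dtype=float).ravel()
    a = np.asarray(a, dtype=float).ravel()
    n = model.n_units
    if u.size != n:
        raise ValueError(f"drive has {u.size} entries, expected {n}")
    if a.size != 2 * model.side:
        raise ValueError(f"output vector has {a.size} entries, expected {2 * model.side}")
    if np.any(u < 0) or np.any(a < 0):
        raise ValueError("drive and output activity must be nonnegative")
    D = build_spanning_basis(model.side)
    drive = u + D.weights @ a          # constant input: u + Da
    dt, tau = model.time_step, model.time_constant
    n_steps = int(round(duration / dt))
    s = np.zeros(n)
    times, states = [0.0], [s.copy()]
    for i in range(1, n_steps + 1):
        s = s + (dt / tau) * (-s + drive)
        if np.max(np.abs(s)) > s_ceiling:
            raise RuntimeError(f"grid state diverged at t={i * dt:.1f} ms")
        if i % record_every == 0 or i == n_steps:
            times.append(i * dt)
            states.append(s.copy())
    return GridTrajectory(times=np.asarray(times), states=np.asarray(states),
                          side=model.side)


def count_hills(rate_grid: np.ndarray, threshold: float = HILL_THRESHOLD):
    """Connected components of supra-threshold activity (4-neighbour).

    Returns ``(n_hills, peak_locations)`` where each location is the (row,
    col) of the component's maximum.  The threshold is a small absolute
    activity level in drive units, so weak secondary hills count as hills.
    """
    active = rate_grid > threshold
    labels, n = ndimage.label(active, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    peaks = []
    for lab in range(1, n + 1):
        masked = np.where(labels == lab, rate_grid, -np.inf)
        peaks.append(tuple(int(v) for v in
                           np.unravel_index(np.argmax(masked), rate_grid.shape)))
    return n, peaks


@dataclass
class ScenarioReport:
    """Steady-state summary of one selection scenario."""

    name: str
    n_hills: int
    hill_locations: list
    peak_activity: float
    rate_grid: np.ndarray = field(repr=False)
    output_vector: np.ndarray = field(repr=False)
    drive: np.ndarray = field(repr=False)


def _scenario_setup(name: str, side: int, drive: float, tonic: float,
                    boost: float, target, competitor):
    """Drive field and output vector for each named scenario."""
    u = np.zeros((side, side))
    a = np.full(2 * side, tonic)
    ti, tj = target
    u[ti, tj] = drive
    if name == "tonic":
        return u, a
    # pause the row and column neurons intersecting at the (first) target
    a[ti] = 0.0
    a[side + tj] = 0.0
    if name == "pause":
        return u, a
    ci, cj = competitor
    if cj != tj:
        raise ValueError("competitor must share the target's column")
    u[ci, cj] = drive
    if name == "competing":
        return u, a
    # competing_corrected: boost the competitor's row neuron above tonic
    a[ci] = boost
    return u, a


def run_scenario(name: str, side: int = 20, drive: float = 1.5,
                 tonic: float = 1.0, boost: float = 2.0,
                 target=(12, 7), competitor=(4, 7),
                 duration: float = 200.0,
                 model: GridModel | None = None) -> ScenarioReport:
    """Simulate one of the four selection scenarios and count activity hills.

    * ``tonic``: uniform tonic inhibition; the target drive is suppressed
      (0 hills).
    * ``pause``: the row and column neurons intersecting at the target
      pause; a single hill forms there (1 hill).
    * ``competing``: a second target on the same column leaks through the
      paused column neuron (2 hills).
    * ``competing_corrected``: the competitor's row neuron increases its
      firing above tonic, restoring single-target selection (1 hill).

    Defaults (drive 1.5, tonic 1) satisfy tonic < drive < 2*tonic, so
    suppression and selection both hold at the fixed point.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; one of {SCENARIOS}")
    model = model or GridModel(side=side)
    u, a = _scenario_setup(name, model.side, drive, tonic, boost,
                           target, competitor)
    traj = simulate_grid(model, u, a, duration=duration)
    grid = traj.final_rate_grid()
    n_hills, locations = count_hills(grid)
    return ScenarioReport(name=name, n_hills=n_hills, hill_locations=locations,
                          peak_activity=float(grid.max()), rate_grid=grid,
                          output_vector=a, drive=u.ravel())


def selectable_coordinates(side: int = 20, drive: float = 1.5,
                           tonic: float = 1.0) -> int:
    """How many grid coordinates can be selected one at a time.

    For each coordinate, pause its row and column neurons under otherwise
    tonic output and check at the fixed point that exactly that cell is
    active.  With tonic < drive < 2*tonic every coordinate is selectable,
    so the count equals side**2 — the quadratic spanning-code capacity.
    """
    if not tonic < drive < 2 * tonic:
        raise ValueError("selection regime requires tonic < drive < 2*tonic")
    count = 0
    for i in range(side):
        for j in range(side):
            u = np.zeros((side, side))
            u[i, j] = drive
            # fixed point without simulation: s* = u - row_a - col_a
            row_a = np.full(side, tonic)
            col_a = np.full(side, tonic)
            row_a[i] = 0.0
            col_a[j] = 0.0
            s_star = u - row_a[:, None] - col_a[None, :]
            r_star = np.maximum(0.0, s_star)
            active = np.argwhere(r_star > HILL_THRESHOLD)
            if len(active) == 1 and tuple(active[0]) == (i, j):
                count += 1
    return count
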