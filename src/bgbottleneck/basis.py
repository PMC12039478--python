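"""Linear-system core of the dynamic-weights model of basal ganglia output.

The model treats the ``n x b`` matrix ``D`` of connection weights from ``b``
inhibitory output neurons to ``n`` target neurons as a set of basis
functions, one column per output neuron.  The vector ``a`` of output firing
rates then acts as a set of dynamic weights on those basis functions, and
the inhibition arriving at the targets is the linear system

    D a = f,   with  D_ij <= 0,  a_i >= 0,  f_i <= 0.

This module constructs basis matrices (shifted prototypes on a ring or
line, row/column spanning codes on a grid, or explicit matrices), applies
and inverts the linear system, analyses rank and solution uniqueness, and
computes the combinatorial coding capacity of the output population.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "BasisPrototype",
    "BasisMatrix",
    "SolveResult",
    "build_shifted_basis",
    "apply_weights",
    "solve_weights",
    "rank_of_basis",
    "count_output_states",
    "spanning_code_capacity",
    "topographic_capacity",
]

TOPOLOGIES = ("ring", "line", "grid_spanning", "explicit")


class RankDeficientBasisWarning(UserWarning):
    """A shifted-prototype construction produced a rank-deficient matrix.

    The shifted construction is usually full rank, but fails for prototypes
    whose discrete Fourier transform has a zero on the relevant frequencies
    (e.g. an all-equal prototype with b = n).
    """


@dataclass(frozen=True)
class BasisPrototype:
    """A single basis function as nonnegative connection-strength magnitudes.

    Parameters
    ----------
    values
        Ordered strengths (dimensionless).  Stored as magnitudes; matrices
        built from a prototype negate them once, so downstream algebra uses
        the inhibitory convention D <= 0.
    center_index
        Position of the peak within ``values``.
    """

    values: np.ndarray
    center_index: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("prototype must be a non-empty 1-D sequence")
        if np.any(vals < 0):
            raise ValueError("prototype magnitudes must be nonnegative")
        if not np.any(vals > 0):
            raise ValueError("prototype must have at least one nonzero value")
        if not 0 <= self.center_index < vals.size:
            raise ValueError("center_index outside prototype support")
        if vals[self.center_index] < vals.max():
            raise ValueError("peak value must be located at center_index")

    @property
    def width(self) -> int:
        return self.values.size

    @property
    def is_symmetric(self) -> bool:
        c = self.center_index
        left = self.values[:c][::-1]
        right = self.values[c + 1:]
        m = min(left.size, right.size)
        if left.size != right.size and (np.any(left[m:] != 0) or np.any(right[m:] != 0)):
            return False
        return bool(np.allclose(left[:m], right[:m]))

    @classmethod
    def step(cls, peak: float = 1.0, step: float = 0.2, n_steps: int = 2) -> "BasisPrototype":
        """Symmetric prototype stepping down from ``peak`` by ``step`` per side.

        ``n_steps=2`` with the defaults gives ``[0.6, 0.8, 1.0, 0.8, 0.6]``,
        the overlapping symmetric basis used in the cortical demonstration.
        """
        side = peak - step * np.arange(1, n_steps + 1)
        if np.any(side < 0):
            raise ValueError("step prototype would go negative; reduce n_steps or step")
        vals = np.concatenate([side[::-1], [peak], side])
        return cls(vals, n_steps)

    @classmethod
    def single(cls, peak: float = 1.0) -> "BasisPrototype":
        """One-point prototype: an output neuron contacting a single target."""
        return cls(np.array([peak]), 0)


@dataclass
class BasisMatrix:
    """The ``n x b`` inhibitory weight matrix D defining the basis functions.

    Every entry is <= 0 (basal ganglia output is GABAergic); column ``i`` is
    the basis function of output neuron ``i``.
    """

    weights: np.ndarray
    topology: str = "explicit"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        W = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if np.any(W > 0):
            raise ValueError("basis matrix entries must be <= 0 (inhibitory)")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}; one of {TOPOLOGIES}")
        if self.topology in ("ring", "line") and W.shape[1] > W.shape[0]:
            raise ValueError("ring/line topologies require b <= n")
        if self.topology == "grid_spanning" and not np.isin(W, (-1.0, 0.0)).all():
            raise ValueError("grid_spanning entries must be in {-1, 0}")
        self.weights = W

    @property
    def n(self) -> int:
        """Number of target neurons (rows)."""
        return self.weights.shape[0]

    @property
    def b(self) -> int:
        """Number of output neurons (columns)."""
        return self.weights.shape[1]

    @classmethod
    def from_magnitudes(cls, magnitudes: np.ndarray, topology: str = "explicit",
                        **meta) -> "BasisMatrix":
        """Build from nonnegative strengths, negating once on storage."""
        M = np.asarray(magnitudes, dtype=float)
        if np.any(M < 0):
            raise ValueError("magnitudes must be nonnegative")
        return cls(-M, topology, dict(meta))

    # -- delimited-text / JSON round trip ------------------------------------
    def to_csv(self, path, sep: str = "\t") -> None:
        header = f"# topology={self.topology} n={self.n} b={self.b}"
        with open(path, "w") as fh:
            fh.write(header + "\n")
            np.savetxt(fh, self.weights, delimiter=sep, fmt="%.12g")

    @classmethod
    def from_csv(cls, path, sep: str = "\t") -> "BasisMatrix":
        with open(path) as fh:
            header = fh.readline().strip()
            topology = "explicit"
            if header.startswith("#"):
                for token in header[1:].split():
                    if token.startswith("topology="):
                        topology = token.split("=", 1)[1]
            W = np.loadtxt(fh, delimiter=sep, ndmin=2)
        return cls(W, topology)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"topology": self.topology,
                       "weights": self.weights.tolist()}, fh)

    @classmethod
    def from_json(cls, path) -> "BasisMatrix":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(np.asarray(payload["weights"]), payload.get("topology", "explicit"))


def build_shifted_basis(prototype: BasisPrototype, b: int, n: int,
                        topology: str = "ring") -> BasisMatrix:
    """Tile ``b`` shifted copies of a prototype over ``n`` targets.

    Column ``i`` places the prototype's peak at target ``i * (n // b)``;
    under ``ring`` topology the support wraps circularly, under ``line`` it
    is truncated at the edges.  Uniform spacing requires ``n`` divisible by
    ``b`` for the ring.

    Raises
    ------
    ValueError
        If ``b > n``, the spacing is non-uniform on a ring, or the shifts
        produce duplicate columns (a degenerate tiling).

    Warns
    -----
    RankDeficientBasisWarning
        If the constructed matrix is not full column rank.  The shifted
        construction usually guarantees linear independence, but not for
        prototypes with vanishing Fourier components.
    """
    if topology not in ("ring", "line"):
        raise ValueError("shifted construction supports ring or line topology")
    if b < 1:
        raise ValueError("need at least one output neuron")
    if b > n:
        raise ValueError(f"cannot tile {b} basis functions over {n} targets (b > n)")
    if topology == "ring" and n % b != 0:
        raise ValueError(f"ring topology needs n divisible by b (got n={n}, b={b})")

    spacing = n // b
    mags = np.zeros((n, b))
    offsets = np.arange(prototype.width) - prototype.center_index
    for i in range(b):
        center = i * spacing
        idx = center + offsets
        if topology == "ring":
            mags[idx % n, i] = prototype.values
        else:
            keep = (idx >= 0) & (idx < n)
            mags[idx[keep], i] = prototype.values[keep]

    for i in range(b):
        for j in range(i + 1, b):
            if np.array_equal(mags[:, i], mags[:, j]):
                raise ValueError("shifted construction produced identical columns")

    D = BasisMatrix.from_magnitudes(mags, topology,
                                    prototype=prototype.values.tolist(),
                                    spacing=spacing)
    if rank_of_basis(D) < b:
        warnings.warn(
            "shifted basis matrix is rank deficient; the prototype's discrete "
            "Fourier transform vanishes on a used frequency",
            RankDeficientBasisWarning, stacklevel=2)
    return D


def _validate_activity(a: np.ndarray, b: int) -> np.ndarray:
    a = np.asarray(a, dtype=float).ravel()
    if a.size != b:
        raise ValueError(f"activity vector has length {a.size}, expected b={b}")
    if np.any(a < 0):
        raise ValueError("output activity must be nonnegative")
    return a


def apply_weights(D: BasisMatrix, a: np.ndarray) -> np.ndarray:
    """Inhibition function f = D a received by the targets.

    ``a`` holds the nonnegative output rates; the result is elementwise
    <= 0 by the sign constraints.
    """
    a = _validate_activity(a, D.b)
    f = D.weights @ a
    # exact product; numerical noise cannot flip the sign since all terms <= 0
    return f


@dataclass(frozen=True)
class SolveResult:
    """Least-squares inversion of D a = f.

    Attributes
    ----------
    activity
        The least-squares solution (may have small negative entries when the
        target function is infeasible).
    residual
        Euclidean norm of D a - f.
    feasible
        True when every entry of ``activity`` is >= -tol: the target
        function is achievable by nonnegative output rates.
    unique
        True when D has full column rank and the residual vanishes, so the
        linear system admits at most one solution.
    """

    activity: np.ndarray
    residual: float
    feasible: bool
    unique: bool


def solve_weights(D: BasisMatrix, f: np.ndarray, tol: float = 1e-8) -> SolveResult:
    """Which output vectors a achieve the target inhibition function f?

    Returns the minimum-norm least-squares solution together with a
    uniqueness certificate: a full-rank D with a vanishing residual has at
    most one solution, so the same target function pins down one pattern of
    output activity.  Infeasibility (negative entries) is reported, not
    raised.
    """
    f = np.asarray(f, dtype=float).ravel()
    if f.size != D.n:
        raise ValueError(f"target function has length {f.size}, expected n={D.n}")
    a, _, rank, _ = np.linalg.lstsq(D.weights, f, rcond=None)
    residual = float(np.linalg.norm(D.weights @ a - f))
    scale = max(1.0, float(np.linalg.norm(f)))
    feasible = bool(np.all(a >= -tol))
    unique = bool(rank == D.b and residual <= tol * scale)
    return SolveResult(a, residual, feasible, unique)


def rank_of_basis(D: BasisMatrix, tol: float | None = None) -> int:
    """Numerical rank of D via its singular values.

    Singular values below ``max(n, b) * eps * sigma_max`` count as zero
    (the standard numerical-rank rule) unless an explicit ``tol`` is given.
    """
    s = np.linalg.svd(D.weights, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    if tol is None:
        tol = max(D.n, D.b) * np.finfo(float).eps * s[0]
    return int(np.count_nonzero(s > tol))


def count_output_states(b: int, states_per_neuron: int) -> int:
    """Exact number of distinct output combinations, ``states ** b``.

    With classic disinhibition each neuron is on/off (2 states); admitting
    increases above tonic as well gives 3 states, so 100 output neurons can
    set more than 5e47 distinct dynamic-weight combinations.  Computed in
    arbitrary-precision integers.
    """
    if b < 0:
        raise ValueError("b must be nonnegative")
    if states_per_neuron < 1:
        raise ValueError("need at least one state per neuron")
    return int(states_per_neuron) ** int(b)


def topographic_capacity(b: int) -> int:
    """Coordinates controllable point-to-point: best case one neuron each."""
    return int(b)


def spanning_code_capacity(b: int, grid_aspect_ratio: float | Fraction = 1.0) -> int:
    """Grid coordinates controllable by a row/column spanning code.

    ``b`` output neurons are split into a row group and a column group in
    proportion to the grid aspect ratio (minor/major axis, in (0, 1];
    ratio 1 is the symmetric split).  Each coordinate is selected by
    pausing one neuron from each group, so capacity is
    ``n_rows * n_cols`` with ``n_rows + n_cols = b`` — quadratic in ``b``
    at ratio 1, versus linear for a topographic map.  At extreme ratios at
    least one neuron is kept on the minority axis (a zero-neuron axis
    controls nothing), so the capacity floor is ``b - 1``.
    """
    if b < 2:
        raise ValueError("a spanning code needs b >= 2 to cover two axes")
    ratio = float(grid_aspect_ratio)
    if not 0 < ratio <= 1:
        raise ValueError("grid_aspect_ratio must lie in (0, 1]")
    minor = int(round(b * ratio / (1.0 + ratio)))
    minor = min(max(minor, 1), b - 1)
    return minor * (b - minor)
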