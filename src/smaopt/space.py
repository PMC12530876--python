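"""Feasible parameter space and sample-set generation.

The optimization searches a box in Lennard-Jones parameter space.  For the
n-octane use case the box is 4-dimensional: the zero-crossing distances
``sigma_C`` and ``sigma_H`` (nm) and the well depths ``eps_C`` and ``eps_H``
(kJ/mol) of the carbon and hydrogen 12-6 pair potentials.  Two families of
designs are supported: full-factorial grids and base-2 Sobol sequences.

Point sets are returned as ``(n, d)`` float arrays in the declared parameter
order; :class:`LJParamSet` is the scalar point type used at API edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import qmc

from .errors import ContractError, ParameterizationError

#: canonical parameter order for the Lennard-Jones use case
LJ_PARAM_NAMES: tuple[str, ...] = ("sigma_C", "sigma_H", "eps_C", "eps_H")

#: relative tolerance used for grid endpoint inclusion
_ENDPOINT_RTOL = 1e-9


@dataclass(frozen=True)
class LJParamSet:
    """One point in the 4-D Lennard-Jones parameter space.

    ``sigma_C``/``sigma_H`` in nm; ``eps_C``/``eps_H`` in kJ/mol.  All values
    must be finite and strictly positive.
    """

    sigma_C: float
    sigma_H: float
    eps_C: float
    eps_H: float

    def __post_init__(self) -> None:
        for name in LJ_PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ContractError(f"{name} must be finite and > 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma_C, self.sigma_H, self.eps_C, self.eps_H])

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "LJParamSet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (4,):
            raise ContractError(f"expected 4 values, got shape {arr.shape}")
        return cls(*arr.tolist())


@dataclass(frozen=True)
class ParameterSpace:
    """An axis-aligned box of feasible parameter values.

    ``names`` fixes the dimension order; ``lower[i] < upper[i]`` must hold for
    every dimension.  Dimensionality is arbitrary (``d >= 1``) although the
    Lennard-Jones workflow uses ``d = 4``.
    """

    names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.lower) == len(self.upper)):
            raise ParameterizationError("names/lower/upper length mismatch")
        if len(self.names) < 1:
            raise ParameterizationError("parameter space needs at least 1 dimension")
        for name, lo, hi in zip(self.names, self.lower, self.upper):
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ParameterizationError(
                    f"dimension {name}: need finite lower < upper, got [{lo}, {hi}]"
                )

    @property
    def ndim(self) -> int:
        return len(self.names)

    def lower_array(self) -> np.ndarray:
        return np.asarray(self.lower, dtype=float)

    def upper_array(self) -> np.ndarray:
        return np.asarray(self.upper, dtype=float)

    def normalize(self, points: np.ndarray) -> np.ndarray:
        """Affinely map points into the unit box [0, 1]^d."""
        lo, hi = self.lower_array(), self.upper_array()
        return (np.asarray(points, dtype=float) - lo) / (hi - lo)

    def denormalize(self, unit_points: np.ndarray) -> np.ndarray:
        lo, hi = self.lower_array(), self.upper_array()
        return lo + np.asarray(unit_points, dtype=float) * (hi - lo)


@dataclass(frozen=True)
class GridSpec:
    """Per-dimension ``(min, step, max)`` triplets of a full-factorial design.

    Each dimension contributes the inclusive arithmetic sequence
    ``min, min + step, ...`` up to ``max`` (endpoint included whenever
    ``max - min`` is an integer multiple of ``step`` within a 1e-9 relative
    tolerance).
    """

    names: tuple[str, ...]
    minima: tuple[float, ...]
    steps: tuple[float, ...]
    maxima: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.minima) == len(self.steps) == len(self.maxima)):
            raise ParameterizationError("grid spec arrays must have equal length")
        for name, lo, st, hi in zip(self.names, self.minima, self.steps, self.maxima):
            if st <= 0:
                raise ParameterizationError(f"dimension {name}: step must be > 0, got {st}")
            if lo > hi:
                raise ParameterizationError(f"dimension {name}: min {lo} > max {hi}")

    def axis_values(self, i: int) -> np.ndarray:
        lo, st, hi = self.minima[i], self.steps[i], self.maxima[i]
        span = hi - lo
        count = int(math.floor(span / st + _ENDPOINT_RTOL * max(1.0, span / st))) + 1
        return lo + st * np.arange(count)

    def counts(self) -> tuple[int, ...]:
        return tuple(len(self.axis_values(i)) for i in range(len(self.names)))


def make_grid(spec: GridSpec) -> np.ndarray:
    """Full Cartesian product of the spec's per-dimension sequences.

    Returns an ``(n, d)`` array ordered lexicographically over the dimensions
    in declared order (first dimension varies slowest).
    """
    axes = [spec.axis_values(i) for i in range(len(spec.names))]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def make_sobol(
    space: ParameterSpace, m: int, scramble_seed: int | None = None
) -> np.ndarray:
    """``2**m`` points of a base-2 Sobol sequence scaled into ``space``.

    Unscrambled by default so the point set is identical across platforms;
    pass ``scramble_seed`` for an Owen-scrambled variant.  Points are returned
    in sequence order.
    """
    if m < 0:
        raise ParameterizationError(f"Sobol exponent m must be >= 0, got {m}")
    if scramble_seed is None:
        engine = qmc.Sobol(d=space.ndim, scramble=False)
    else:
        engine = qmc.Sobol(d=space.ndim, scramble=True, seed=scramble_seed)
    unit = engine.random_base2(m=m)
    return qmc.scale(unit, space.lower_array(), space.upper_array())


def contains(space: ParameterSpace, p: "LJParamSet | np.ndarray") -> bool | np.ndarray:
    """Inclusive box membership; accepts a scalar point or an ``(n, d)`` batch."""
    arr = p.as_array() if isinstance(p, LJParamSet) else np.asarray(p, dtype=float)
    if arr.shape[-1] != space.ndim:
        raise ContractError(
            f"point dimensionality {arr.shape[-1]} != space dimensionality {space.ndim}"
        )
    lo, hi = space.lower_array(), space.upper_array()
    inside = np.all((arr >= lo) & (arr <= hi), axis=-1)
    return bool(inside) if inside.ndim == 0 else inside


def lj_acquisition_space() -> ParameterSpace:
    """The feasible box used for training-data acquisition.

    Bounds chosen wide enough to cover physically and numerically stable
    alkane Lennard-Jones parameters.
    """
    return ParameterSpace(
        names=LJ_PARAM_NAMES,
        lower=(0.0500, 0.0450, 0.1500, 0.0100),
        upper=(0.3500, 0.3500, 1.1500, 0.1500),
    )


def reference_sample_specs() -> dict[str, GridSpec | tuple[ParameterSpace, int]]:
    """The four standard sample-set designs of the density study.

    Two full-factorial grids ("Grid1296" with 6 values per dimension,
    "Grid2401" with 7) and two ``2**11``-point Sobol sequences over slightly
    different boxes.  Grid entries are :class:`GridSpec`; Sobol entries are
    ``(ParameterSpace, m)`` pairs.
    """
    return {
        "Grid1296": GridSpec(
            names=LJ_PARAM_NAMES,
            minima=(0.0750, 0.0683, 0.2465, 0.0300),
            steps=(0.0500, 0.0455, 0.1643, 0.0200),
            maxima=(0.3250, 0.2958, 1.0680, 0.1300),
        ),
        "Grid2401": GridSpec(
            names=LJ_PARAM_NAMES,
            minima=(0.0500, 0.0455, 0.1643, 0.0200),
            steps=(0.0500, 0.0455, 0.1643, 0.0200),
            maxima=(0.3500, 0.3185, 1.1501, 0.1400),
        ),
        "Sobol1": (
            ParameterSpace(
                names=LJ_PARAM_NAMES,
                lower=(0.0500, 0.0450, 0.1500, 0.0200),
                upper=(0.3500, 0.3200, 1.1500, 0.1400),
            ),
            11,
        ),
        "Sobol2": (
            ParameterSpace(
                names=LJ_PARAM_NAMES,
                lower=(0.0500, 0.0450, 0.1500, 0.0100),
                upper=(0.3500, 0.3500, 1.1500, 0.1500),
            ),
            11,
        ),
    }
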