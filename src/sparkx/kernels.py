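"""Coordinate standardization and the eleven coordinate transformations.

The covariance test projects expression onto the column space of a (possibly
transformed) coordinate matrix. Power against focal and periodic patterns
comes from Gaussian- and cosine-transformed coordinates whose smoothness /
periodicity parameters are set from empirical quantiles of the absolute
standardized coordinates, making the whole kernel set invariant to any
rescaling of the raw coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import Coordinates

__all__ = [
    "KernelSpec",
    "TransformedCoordinates",
    "standardize",
    "standardize_coordinates",
    "quantile_params",
    "gaussian_transform",
    "cosine_transform",
    "default_kernel_set",
    "DEFAULT_LEVELS",
]

DEFAULT_LEVELS = (0.2, 0.4, 0.6, 0.8, 1.0)


class DegenerateInputError(ValueError):
    """Constant vector: cannot be standardized; caller should skip the gene."""


@dataclass(frozen=True)
class KernelSpec:
    """One coordinate transformation: identity, gaussian (smoothness sigma per
    axis) or cosine (period phi per axis)."""

    kind: str  # identity | gaussian | cosine
    params: tuple[float, ...]
    label: str

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "gaussian", "cosine"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind != "identity" and any(p <= 0 for p in self.params):
            raise ValueError("kernel parameters must be strictly positive")


@dataclass
class TransformedCoordinates:
    positions: np.ndarray  # n x d
    spec: KernelSpec


def standardize(v: np.ndarray) -> np.ndarray:
    """Center and scale to mean 0, sample standard deviation 1 (n-1 denominator)."""
    v = np.asarray(v, dtype=float).ravel()
    if v.size < 3:
        raise ValueError("need at least 3 observations to standardize")
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("constant vector cannot be standardized")
    return (v - v.mean()) / sd


def standardize_coordinates(c: Coordinates | np.ndarray) -> np.ndarray:
    """Standardize each coordinate axis independently (mean 0, sample sd 1)."""
    pos = c.positions if isinstance(c, Coordinates) else np.asarray(c, float)
    return np.column_stack([standardize(pos[:, j]) for j in range(pos.shape[1])])


def quantile_params(s: np.ndarray, levels=DEFAULT_LEVELS) -> np.ndarray:
    """Per-axis quantiles of |standardized coordinate| at the given levels.

    Returns a (len(levels), d) array; linear-interpolation order statistics,
    level 1.0 being the axis maximum. A zero quantile (possible when an axis
    has many exact zeros) is replaced by the smallest positive absolute value
    so downstream transformation parameters stay strictly positive.
    """
    s = np.atleast_2d(np.asarray(s, float))
    levels = np.asarray(levels, float)
    if np.any(levels <= 0) or np.any(levels > 1):
        raise ValueError("quantile levels must lie in (0, 1]")
    a = np.abs(s)
    q = np.quantile(a, levels, axis=0)
    if np.any(q <= 0):
        for j in range(a.shape[1]):
            pos = a[:, j][a[:, j] > 0]
            if pos.size == 0:
                raise ValueError(f"coordinate axis {j} is identically zero")
            bad = q[:, j] <= 0
            if bad.any():
                warnings.warn(
                    f"zero quantile on axis {j}; using smallest positive |value|"
                )
                q[bad, j] = pos.min()
    return q


def gaussian_transform(s: np.ndarray, sigma) -> np.ndarray:
    """Entrywise exp(-s^2 / (2 sigma^2)); values in (0, 1]."""
    sigma = np.asarray(sigma, float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    return np.exp(-np.square(s) / (2.0 * np.square(sigma)))


def cosine_transform(s: np.ndarray, phi) -> np.ndarray:
    """Entrywise cos(2 pi s / phi); values in [-1, 1]."""
    phi = np.asarray(phi, float)
    if np.any(phi <= 0):
        raise ValueError("phi must be strictly positive")
    return np.cos(2.0 * np.pi * s / phi)


def default_kernel_set(
    c: Coordinates | np.ndarray,
    levels=DEFAULT_LEVELS,
    include_identity: bool = True,
    kinds=("gaussian", "cosine"),
) -> list[TransformedCoordinates]:
    """The default kernel set: identity plus, per quantile level, one Gaussian
    and one cosine transformation (11 kernels for the default 5 levels).

    The k-th Gaussian (cosine) kernel uses the k-th |coordinate| quantile on
    every axis simultaneously; quantiles are taken per axis, so the two axes
    generally carry different parameters within one kernel.
    """
    s = standardize_coordinates(c)
    q = quantile_params(s, levels)
    out: list[TransformedCoordinates] = []
    if include_identity:
        out.append(
            TransformedCoordinates(s.copy(), KernelSpec("identity", (), "identity"))
        )
    for kind, fn in (("gaussian", gaussian_transform), ("cosine", cosine_transform)):
        if kind not in kinds:
            continue
        for k in range(len(levels)):
            params = tuple(q[k])
            spec = KernelSpec(kind, params, f"{kind}_{k + 1}")
            out.append(TransformedCoordinates(fn(s, q[k]), spec))
    return out
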