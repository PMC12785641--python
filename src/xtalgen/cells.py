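"""Unit-cell volume sampling and bounded cell-length derivation.

This module provides

* the two volume distributions used to drive cell generation (log-normal
  fitted to database statistics, and uniform),
* the analytic probability density of the volume of an orthorhombic cell
  whose three edge lengths are drawn independently from ``U(l, u)`` (used
  as a validation reference),
* the constrained derivation of ordered cell lengths ``a1 <= a2 <= a3``
  from a sampled volume, honouring length bounds and a maximum adjacent
  ratio ``r`` (``a2/a1 <= r`` and ``a3/a2 <= r``),
* a maximum-likelihood log-normal fit for user-supplied volume samples.

All lengths are in Angstrom, volumes in cubic Angstrom.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "VolumeSpec",
    "CellBounds",
    "CellLengths",
    "sample_volume",
    "sample_volume_feasible",
    "pdf_volume_uniform_cells",
    "cdf_volume_uniform_cells",
    "cell_from_volume",
    "permute_lengths",
    "sample_cell_uniform",
    "fit_lognormal",
    "read_volume_file",
]


@dataclass(frozen=True)
class VolumeSpec:
    """Parameters of the unit-cell volume distribution.

    ``family='lognormal'`` uses ``mu``/``sigma`` (mean and standard
    deviation of ``ln V``); ``family='uniform'`` uses ``vmin``/``vmax``.
    """

    family: str = "lognormal"
    mu: float = 6.04
    sigma: float = 0.394
    vmin: float = 160.0
    vmax: float = 1000.0

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "uniform"):
            raise ConfigurationError(f"unknown volume family {self.family!r}")
        if self.family == "lognormal" and not self.sigma > 0:
            raise ConfigurationError(f"sigma must be > 0, got {self.sigma}")
        if self.family == "uniform" and not 0 < self.vmin < self.vmax:
            raise ConfigurationError(
                f"need 0 < vmin < vmax, got ({self.vmin}, {self.vmax})"
            )


@dataclass(frozen=True)
class CellBounds:
    """Cell-length bounds and maximum adjacent length ratio."""

    lmin: float = 4.0
    lmax: float = 10.0
    max_ratio: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.lmin <= self.lmax:
            raise ConfigurationError(
                f"need 0 < lmin <= lmax, got ({self.lmin}, {self.lmax})"
            )
        if not self.max_ratio >= 1:
            raise ConfigurationError(f"max_ratio must be >= 1, got {self.max_ratio}")


class CellLengths(NamedTuple):
    a1: float
    a2: float
    a3: float


def sample_volume(spec: VolumeSpec, rng: np.random.Generator) -> float:
    """Draw one volume from the configured distribution."""
    if spec.family == "lognormal":
        return float(np.exp(rng.normal(spec.mu, spec.sigma)))
    return float(rng.uniform(spec.vmin, spec.vmax))


def sample_volume_feasible(
    spec: VolumeSpec,
    bounds: CellBounds,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> float:
    """Resample until the volume is feasible for ``bounds`` (truncation).

    A volume is feasible iff it lies within ``[lmin^3, lmax^3]``; any such
    volume admits lengths satisfying the ratio constraint (the cube
    ``a1 = a2 = a3 = V^(1/3)`` always does).
    """
    lo, hi = bounds.lmin**3, bounds.lmax**3
    for _ in range(max_tries):
        v = sample_volume(spec, rng)
        if lo <= v <= hi:
            return v
    raise DomainError(
        f"no feasible volume in [{lo:g}, {hi:g}] after {max_tries} draws; "
        "volume distribution and cell bounds are incompatible"
    )


def _log_sum_pdf(c: np.ndarray, lam: float, ups: float) -> np.ndarray:
    """Density of ``B1+B2+B3`` where ``B_i = ln A_i``, ``A_i ~ U(l, u)``.

    Each ``B_i`` has density ``e^b / (u - l)`` on ``[lam, ups]``
    (``lam = ln l``, ``ups = ln u``).  Convolving two of them gives
    ``e^c * L(c) / (u-l)^2`` with ``L`` the triangular overlap length on
    ``[2 lam, 2 ups]``; convolving in the third integrates the triangle
    over a sliding window, which has a closed piecewise-quadratic form.
    """
    w = ups - lam
    span = np.exp(ups) - np.exp(lam)  # u - l

    def tent_integral(b: np.ndarray) -> np.ndarray:
        # antiderivative of the tent min(b - 2*lam, 2*ups - b) on [2lam, 2ups]
        b = np.clip(b, 2 * lam, 2 * ups)
        mid = lam + ups
        left = 0.5 * (b - 2 * lam) ** 2
        right = w**2 - 0.5 * (2 * ups - b) ** 2
        return np.where(b <= mid, left, right)

    lo = np.maximum(2 * lam, c - ups)
    hi = np.minimum(2 * ups, c - lam)
    window = np.maximum(tent_integral(hi) - tent_integral(lo), 0.0)
    out = np.exp(c) * window / span**3
    return np.where((c >= 3 * lam) & (c <= 3 * ups), out, 0.0)


def pdf_volume_uniform_cells(v, l: float, u: float):
    """p.d.f. of ``V = A1 A2 A3`` with independent ``A_i ~ U(l, u)``.

    Derived through the log transform: ``ln V`` is a sum of three i.i.d.
    variables with known density, whose double convolution is available in
    closed form; the change of variables back to ``V`` divides by ``v``.
    Zero outside ``[l^3, u^3]``; integrates to 1.
    """
    if not 0 < l < u:
        raise DomainError(f"need 0 < l < u, got ({l}, {u})")
    v = np.asarray(v, dtype=float)
    scalar = v.ndim == 0
    v = np.atleast_1d(v)
    out = np.zeros_like(v)
    pos = v > 0
    out[pos] = _log_sum_pdf(np.log(v[pos]), np.log(l), np.log(u)) / v[pos]
    return float(out[0]) if scalar else out


def cdf_volume_uniform_cells(v, l: float, u: float, n_grid: int = 200_001):
    """c.d.f. matching :func:`pdf_volume_uniform_cells`.

    Computed once on a dense log-spaced grid by trapezoidal accumulation
    and evaluated by interpolation; accuracy far exceeds Monte-Carlo
    comparison needs (grid error ~ (range/n)^2).
    """
    if not 0 < l < u:
        raise DomainError(f"need 0 < l < u, got ({l}, {u})")
    c_grid = np.linspace(3 * np.log(l), 3 * np.log(u), n_grid)
    dens = _log_sum_pdf(c_grid, np.log(l), np.log(u))
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(c_grid))]
    )
    cum /= cum[-1]
    v_arr = np.asarray(v, dtype=float)
    scalar = v_arr.ndim == 0
    v_arr = np.atleast_1d(v_arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        logv = np.where(v_arr > 0, np.log(np.where(v_arr > 0, v_arr, 1.0)), -np.inf)
    out = np.interp(logv, c_grid, cum, left=0.0, right=1.0)
    return float(out[0]) if scalar else out


def _a1_interval(volume: float, b: CellBounds) -> tuple[float, float]:
    r = b.max_ratio
    hi = min(b.lmax, volume ** (1.0 / 3.0))
    lo = max(
        b.lmin,
        volume / b.lmax**2,
        (volume / r**3) ** (1.0 / 3.0),
        # ensure a feasible a2 exists: lower(a2) = V/(a1*lmax) must not
        # exceed upper(a2) = r*a1
        (volume / (r * b.lmax)) ** 0.5,
    )
    return lo, hi


def cell_from_volume(
    volume: float, bounds: CellBounds, rng: np.random.Generator
) -> CellLengths:
    """Derive ordered cell lengths ``a1 <= a2 <= a3`` with product ``volume``.

    ``a1`` is drawn uniformly from its feasible interval, then ``a2`` from
    the interval implied by the choice of ``a1``; ``a3 = V/(a1 a2)`` then
    satisfies every constraint by construction: all lengths within
    ``[lmin, lmax]`` and adjacent ratios at most ``max_ratio``.
    """
    r = bounds.max_ratio
    if volume < bounds.lmin**3 * (1 - 1e-12):
        raise DomainError(
            f"volume {volume:g} below lmin^3 = {bounds.lmin**3:g}: cannot keep "
            f"all lengths >= lmin"
        )
    if volume > bounds.lmax**3 * (1 + 1e-12):
        raise DomainError(
            f"volume {volume:g} above lmax^3 = {bounds.lmax**3:g}: cannot keep "
            f"all lengths <= lmax"
        )
    lo1, hi1 = _a1_interval(volume, bounds)
    lo1 = min(lo1, hi1)  # guard rounding at the corners of the feasible set
    a1 = float(rng.uniform(lo1, hi1))

    lo2 = max(a1, (volume / (r * a1)) ** 0.5, volume / (a1 * bounds.lmax))
    hi2 = min(r * a1, bounds.lmax, (volume / a1) ** 0.5)
    lo2 = min(lo2, hi2)
    a2 = float(rng.uniform(lo2, hi2))

    a3 = volume / (a1 * a2)
    return CellLengths(a1, a2, a3)


def permute_lengths(lengths: CellLengths, rng: np.random.Generator) -> CellLengths:
    """Randomly permute the three lengths (all 6 orders equally likely)."""
    order = rng.permutation(3)
    arr = np.asarray(lengths, dtype=float)[order]
    return CellLengths(*arr)


def sample_cell_uniform(bounds: CellBounds, rng: np.random.Generator) -> CellLengths:
    """Three independent ``U(lmin, lmax)`` draws; no ratio/volume constraint."""
    return CellLengths(*rng.uniform(bounds.lmin, bounds.lmax, size=3))


def fit_lognormal(volumes: Iterable[float]) -> tuple[float, float]:
    """Maximum-likelihood log-normal fit: mean and s.d. of ``ln V``."""
    v = np.asarray(list(volumes), dtype=float)
    if v.size < 2:
        raise DomainError(f"need at least 2 values, got {v.size}")
    if np.any(v <= 0):
        raise DomainError("volumes must be strictly positive")
    logs = np.log(v)
    return float(logs.mean()), float(logs.std(ddof=0))


def read_volume_file(path: str | Path) -> np.ndarray:
    """Read a one-volume-per-line plain-text sample (blank lines, '#' comments ok)."""
    values = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            values.append(float(line))
    return np.asarray(values, dtype=float)
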