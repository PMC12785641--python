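"""Reflection lists, structure factors and centrosymmetric phases.

Structure factors are computed over the symmetry-expanded unit cell as

    F(hkl) = sum_j f_j(s) * exp(-2 pi^2 U_j / d^2) * exp(2 pi i h.x_j)

with the 4-Gaussian analytic scattering factors f_j(s), s = sin(theta)/
lambda = 1/(2d).  For a centrosymmetric structure with the inversion at
the origin the imaginary part vanishes identically, so the ground-truth
phase is binary: 0 when Re F >= 0, pi otherwise.  Dispersion corrections
are deliberately omitted to keep the phases exactly binary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DomainError
from .placement import CrystalStructure, _data_path
from .symmetry import expand_to_unit_cell

__all__ = [
    "ReflectionSet",
    "FormFactorTable",
    "DiffractionConfig",
    "reflection_list",
    "scattering_factor",
    "debye_waller",
    "structure_factors",
    "apply_completeness",
    "to_grid",
    "from_grid",
]


@dataclass(frozen=True)
class DiffractionConfig:
    """Resolution, completeness and index-cap settings."""

    d_min: float = 1.0
    completeness: float = 1.0
    sample_resolution: bool = False
    resolution_range: tuple[float, float] = (1.0, 2.0)
    sample_completeness: bool = False
    completeness_range: tuple[float, float] = (0.85, 1.0)
    index_cap: int = 10

    def __post_init__(self) -> None:
        if not self.d_min > 0:
            raise ConfigurationError(f"d_min must be > 0, got {self.d_min}")
        if not 0.0 < self.completeness <= 1.0:
            raise ConfigurationError(
                f"completeness must be in (0, 1], got {self.completeness}"
            )
        if self.index_cap < 1:
            raise ConfigurationError(f"index_cap must be >= 1, got {self.index_cap}")

    def drawn(self, rng: np.random.Generator) -> "DiffractionConfig":
        """Per-structure resolution/completeness draws, when enabled."""
        d_min = self.d_min
        comp = self.completeness
        if self.sample_resolution:
            d_min = float(rng.uniform(*self.resolution_range))
        if self.sample_completeness:
            comp = float(rng.uniform(*self.completeness_range))
        return DiffractionConfig(
            d_min=d_min,
            completeness=comp,
            index_cap=self.index_cap,
        )


@dataclass
class ReflectionSet:
    """Friedel-unique reflections with amplitudes and binary phases."""

    hkl: np.ndarray  # (N, 3) int
    d: np.ndarray  # (N,) Angstrom
    amplitude: np.ndarray = field(default_factory=lambda: np.empty(0))
    phase: np.ndarray = field(default_factory=lambda: np.empty(0))  # radians, 0 or pi

    def __len__(self) -> int:
        return len(self.hkl)


class FormFactorTable:
    """4-Gaussian X-ray scattering factors, loaded from package data."""

    def __init__(self, coefficients: dict[str, np.ndarray]):
        # each value: [a1, b1, a2, b2, a3, b3, a4, b4, c]
        self.coefficients = coefficients

    @classmethod
    def default(cls) -> "FormFactorTable":
        return cls.from_file(_data_path("form_factors.tsv"))

    @classmethod
    def from_file(cls, path) -> "FormFactorTable":
        coeffs: dict[str, np.ndarray] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            coeffs[parts[0]] = np.asarray([float(x) for x in parts[1:]])
        return cls(coeffs)

    def __contains__(self, element: str) -> bool:
        return element in self.coefficients

    def evaluate(self, element: str, s) -> np.ndarray:
        """f(s) with s = sin(theta)/lambda in 1/Angstrom."""
        try:
            v = self.coefficients[element]
        except KeyError:
            raise ConfigurationError(f"no scattering factors for element {element!r}")
        s2 = np.square(np.asarray(s, dtype=float))
        a, b, c = v[0:8:2], v[1:8:2], v[8]
        return np.sum(a * np.exp(-b * s2[..., None]), axis=-1) + c


def scattering_factor(element: str, s, table: FormFactorTable | None = None):
    """Analytic scattering factor; scalar in, scalar out."""
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise DomainError("s = sin(theta)/lambda must be >= 0")
    table = table or FormFactorTable.default()
    out = table.evaluate(element, s_arr)
    return float(out) if np.ndim(s) == 0 else out


def debye_waller(u_iso: float, d: float):
    """Isotropic attenuation exp(-2 pi^2 U / d^2)."""
    u = np.asarray(u_iso, dtype=float)
    d_arr = np.asarray(d, dtype=float)
    if np.any(u < 0):
        raise DomainError("u_iso must be >= 0")
    if np.any(d_arr <= 0):
        raise DomainError("d must be > 0")
    out = np.exp(-2.0 * math.pi**2 * u / np.square(d_arr))
    if np.ndim(u_iso) == 0 and np.ndim(d) == 0:
        return float(out)
    return out


def d_spacings(vectors: np.ndarray, hkl: np.ndarray) -> np.ndarray:
    """d(hkl) from the reciprocal metric of a (possibly skewed) cell."""
    recip = np.linalg.inv(np.asarray(vectors, dtype=float))  # columns a*, b*, c*
    g = np.asarray(hkl, dtype=float) @ recip.T
    return 1.0 / np.linalg.norm(g, axis=-1)


def reflection_list(vectors: np.ndarray, config: DiffractionConfig) -> ReflectionSet:
    """All Friedel-unique reflections with d >= d_min within the index cap.

    One representative per +/-(h,k,l): h > 0, or h = 0 and k > 0, or
    h = k = 0 and l > 0.  (0,0,0) is excluded.
    """
    cap = config.index_cap
    h = np.arange(0, cap + 1)
    k = np.arange(-cap, cap + 1)
    l = np.arange(-cap, cap + 1)
    hh, kk, ll = np.meshgrid(h, k, l, indexing="ij")
    hkl = np.stack([hh, kk, ll], axis=-1).reshape(-1, 3)
    keep = (hkl[:, 0] > 0) | (
        (hkl[:, 0] == 0) & ((hkl[:, 1] > 0) | ((hkl[:, 1] == 0) & (hkl[:, 2] > 0)))
    )
    hkl = hkl[keep]
    d = d_spacings(vectors, hkl)
    sel = d >= config.d_min * (1 - 1e-12)
    return ReflectionSet(hkl=hkl[sel].astype(int), d=d[sel])


def structure_factors(
    structure: CrystalStructure,
    reflections: ReflectionSet,
    table: FormFactorTable | None = None,
) -> ReflectionSet:
    """Amplitudes |F| and binary phases over the expanded unit cell.

    Asserts centrosymmetry numerically: |Im F| must stay below
    1e-8 * max(1, |F|) for every reflection.  Amplitudes below 1e-10 get
    phase 0 by convention.
    """
    table = table or FormFactorTable.default()
    frac = np.asarray([a.frac for a in structure.atoms], dtype=float)
    if len(structure.atoms) == 0:
        raise DomainError("structure has no atoms")
    full_frac, parent = expand_to_unit_cell(frac, structure.group)
    elements = [structure.atoms[i].element for i in parent]
    u_iso = np.asarray([structure.atoms[i].u_iso for i in parent])

    s = 1.0 / (2.0 * reflections.d)  # (N,)
    dw = np.exp(-2.0 * math.pi**2 * np.outer(1.0 / reflections.d**2, u_iso))  # (N, M)
    f = np.empty((len(reflections), len(elements)))
    for el in set(elements):
        cols = [j for j, e in enumerate(elements) if e == el]
        f[:, cols] = table.evaluate(el, s)[:, None]
    phase_arg = 2.0 * math.pi * (reflections.hkl @ full_frac.T)  # (N, M)
    contrib = f * dw
    re = np.sum(contrib * np.cos(phase_arg), axis=1)
    im = np.sum(contrib * np.sin(phase_arg), axis=1)

    amplitude = np.hypot(re, im)
    if structure.group.name == "P-1":
        bad = np.abs(im) > 1e-8 * np.maximum(1.0, amplitude)
        if np.any(bad):
            raise AssertionError(
                "centrosymmetric structure produced a non-real structure factor; "
                "inversion center is not at the origin"
            )
        amplitude = np.abs(re)
    phase = np.where((re < 0) & (amplitude >= 1e-10), math.pi, 0.0)
    return ReflectionSet(
        hkl=reflections.hkl.copy(),
        d=reflections.d.copy(),
        amplitude=amplitude,
        phase=phase,
    )


def total_electrons(structure: CrystalStructure, table: FormFactorTable | None = None) -> float:
    """Electron count of the full cell (the s -> 0 limit of F)."""
    table = table or FormFactorTable.default()
    frac = np.asarray([a.frac for a in structure.atoms], dtype=float)
    _, parent = expand_to_unit_cell(frac, structure.group)
    return float(
        sum(table.evaluate(structure.atoms[i].element, 0.0) for i in parent)
    )


def apply_completeness(
    refs: ReflectionSet, config: DiffractionConfig, rng: np.random.Generator
) -> ReflectionSet:
    """Keep round(completeness * N) reflections, uniformly without replacement."""
    frac = config.completeness
    if not 0.0 < frac <= 1.0:
        raise DomainError(f"completeness must be in (0, 1], got {frac}")
    n = len(refs)
    keep = int(round(frac * n))
    if keep >= n:
        return refs
    idx = np.sort(rng.choice(n, size=keep, replace=False))
    return ReflectionSet(
        hkl=refs.hkl[idx],
        d=refs.d[idx],
        amplitude=refs.amplitude[idx] if len(refs.amplitude) else refs.amplitude,
        phase=refs.phase[idx] if len(refs.phase) else refs.phase,
    )


def to_grid(refs: ReflectionSet, config: DiffractionConfig) -> tuple[np.ndarray, np.ndarray]:
    """Dense hemisphere grids of shape (cap+1, 2 cap+1, 2 cap+1).

    Index mapping: ``grid[h, k + cap, l + cap]``; absent reflections carry
    zero amplitude.  Inverse of :func:`from_grid` on complete data.
    """
    cap = config.index_cap
    if np.any(np.abs(refs.hkl) > cap):
        raise DomainError(f"reflection index exceeds cap {cap}; pre-filter first")
    amp = np.zeros((cap + 1, 2 * cap + 1, 2 * cap + 1))
    pha = np.zeros_like(amp)
    h, k, l = refs.hkl.T
    amp[h, k + cap, l + cap] = refs.amplitude
    pha[h, k + cap, l + cap] = refs.phase
    return amp, pha


def from_grid(
    amp: np.ndarray, pha: np.ndarray, vectors: np.ndarray, config: DiffractionConfig
) -> ReflectionSet:
    """Rebuild the record list from grids (nonzero-amplitude entries)."""
    cap = config.index_cap
    h, k, l = np.nonzero(amp)
    hkl = np.stack([h, k - cap, l - cap], axis=-1).astype(int)
    return ReflectionSet(
        hkl=hkl,
        d=d_spacings(vectors, hkl),
        amplitude=amp[h, k, l],
        phase=pha[h, k, l],
    )
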