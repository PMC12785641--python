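"""Lattice-vector construction and monoclinic/triclinic skew transforms.

Lattice vectors are represented as a 3x3 float array whose ROWS are the
Cartesian a-, b- and c-vectors (right-handed, positive determinant).

Two families of oblique transforms are provided:

* volume-preserving shears (``skew_monoclinic``, ``skew_triclinic``):
  unimodular row operations that leave the determinant untouched while
  opening the inter-axial angles; the monoclinic shear (b-unique setting)
  keeps |a| and |b| fixed and scales |c| by ``sqrt(1 + t^2)``, producing
  ``beta = 90 deg + arctan(t)`` (obtuse setting, ``t >= 0``);
* a length-preserving construction (``apply_length_preserving``) that
  rebuilds the cell from target angles at the original lengths, changing
  the volume instead.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .cells import CellBounds, CellLengths
from .errors import ConfigurationError, DomainError

__all__ = [
    "CellParameters",
    "SkewConfig",
    "vectors_from_lengths",
    "skew_monoclinic",
    "skew_triclinic",
    "sample_skew_t",
    "apply_length_preserving",
    "vectors_from_parameters",
    "parameters_from_vectors",
    "cell_volume",
]

LATTICE_KINDS = ("orthorhombic", "monoclinic", "triclinic")
T_MODES = ("t_uniform", "t_uniform_adjusted", "t_exponential")

# default exponential rate: ln 2 / tan(5 deg) puts the median skew angle
# near 95 deg, matching database monoclinic-angle statistics
DEFAULT_RATE = math.log(2.0) / math.tan(math.radians(5.0))


class CellParameters(NamedTuple):
    """Conventional cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float


@dataclass(frozen=True)
class SkewConfig:
    """How oblique cells are produced from orthorhombic ones."""

    lattice_kind: str = "triclinic"
    beta_max: float = 125.0
    t_mode: str = "t_exponential"
    rate: float = DEFAULT_RATE
    kappa: float = 0.5  # adjusted-mode lower-bound extension factor
    length_preserving: bool = False

    def __post_init__(self) -> None:
        if self.lattice_kind not in LATTICE_KINDS:
            raise ConfigurationError(f"unknown lattice kind {self.lattice_kind!r}")
        if self.t_mode not in T_MODES:
            raise ConfigurationError(f"unknown t mode {self.t_mode!r}")
        if not 90.0 < self.beta_max < 180.0:
            raise ConfigurationError(f"beta_max must be in (90, 180), got {self.beta_max}")
        if not self.rate > 0:
            raise ConfigurationError(f"rate must be > 0, got {self.rate}")
        if not self.kappa >= 0:
            raise ConfigurationError(f"kappa must be >= 0, got {self.kappa}")


def vectors_from_lengths(lengths: CellLengths) -> np.ndarray:
    """Axis-aligned orthorhombic embedding: diagonal cell matrix."""
    arr = np.asarray(lengths, dtype=float)
    if np.any(arr <= 0):
        raise DomainError(f"lengths must be positive, got {tuple(arr)}")
    return np.diag(arr)


def skew_monoclinic(vectors: np.ndarray, t: float) -> np.ndarray:
    """Unimodular b-unique shear: c' = c - t*|c|*a_hat.

    Leaves |a|, |b| and the volume unchanged, scales |c| by
    ``sqrt(1 + t^2)`` and yields ``beta = 90 deg + arctan(t)`` for an
    orthorhombic input (obtuse convention).
    """
    v = np.asarray(vectors, dtype=float)
    a_hat = v[0] / np.linalg.norm(v[0])
    c_len = np.linalg.norm(v[2])
    out = v.copy()
    out[2] = v[2] - t * c_len * a_hat
    return out


def skew_triclinic(
    vectors: np.ndarray, t_ab: float, t_ac: float, t_bc: float
) -> np.ndarray:
    """Unimodular shear with three parameters; reduces to the monoclinic
    shear when ``t_ab = t_bc = 0``.

    b' = b - t_ab*|b|*a_hat;  c' = c - t_ac*|c|*a_hat - t_bc*|c|*b_hat
    (hats taken on the input axes).  Each row gains only multiples of the
    other input rows, so the determinant (volume) is unchanged.
    """
    v = np.asarray(vectors, dtype=float)
    a_hat = v[0] / np.linalg.norm(v[0])
    b_hat = v[1] / np.linalg.norm(v[1])
    b_len = np.linalg.norm(v[1])
    c_len = np.linalg.norm(v[2])
    out = v.copy()
    out[1] = v[1] - t_ab * b_len * a_hat
    out[2] = v[2] - t_ac * c_len * a_hat - t_bc * c_len * b_hat
    return out


def sample_skew_t(
    config: SkewConfig,
    c_len: float,
    bounds: CellBounds,
    rng: np.random.Generator,
) -> float:
    """Draw the shear parameter ``t`` within the admissible range.

    The upper limit combines the angular cap ``tan(beta_max - 90 deg)``
    with the length cap ``sqrt((lmax/c_len)^2 - 1)`` that keeps the
    sheared axis within the configured bounds.
    """
    if c_len > bounds.lmax * (1 + 1e-12):
        raise DomainError(f"axis length {c_len:g} exceeds lmax {bounds.lmax:g}")
    t_angle = math.tan(math.radians(config.beta_max - 90.0))
    t_length = math.sqrt(max((bounds.lmax / c_len) ** 2 - 1.0, 0.0))
    t_hi = min(t_angle, t_length)
    if t_hi <= 0:
        return 0.0
    if config.t_mode == "t_uniform":
        return float(rng.uniform(0.0, t_hi))
    if config.t_mode == "t_uniform_adjusted":
        # extend the interval below zero and clamp: piles probability mass
        # at t = 0 (beta = 90 deg), concentrating the angle histogram near
        # 90 deg; an approximation of the adjusted lower-bound scheme
        return float(max(rng.uniform(-config.kappa * t_hi, t_hi), 0.0))
    # truncated exponential on [0, t_hi] by inverse-c.d.f. sampling
    u = rng.uniform()
    return float(-math.log1p(-u * (1.0 - math.exp(-config.rate * t_hi))) / config.rate)


def vectors_from_parameters(params: CellParameters) -> np.ndarray:
    """Standard crystallographic frame: a along x, b in the xy-plane."""
    a, b, c, alpha, beta, gamma = params
    if min(a, b, c) <= 0:
        raise DomainError("cell lengths must be positive")
    ca, cb, cg = (math.cos(math.radians(x)) for x in (alpha, beta, gamma))
    sg = math.sin(math.radians(gamma))
    if sg <= 0:
        raise DomainError(f"gamma = {gamma} deg gives a degenerate cell")
    v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if v2 <= 0:
        raise DomainError(
            f"angles ({alpha}, {beta}, {gamma}) do not define a positive-definite metric"
        )
    return np.array(
        [
            [a, 0.0, 0.0],
            [b * cg, b * sg, 0.0],
            [c * cb, c * (ca - cb * cg) / sg, c * math.sqrt(v2) / sg],
        ]
    )


def apply_length_preserving(lengths: CellLengths, target: CellParameters) -> np.ndarray:
    """Build lattice vectors at the given lengths and the target's angles.

    The output lengths equal the inputs exactly; the volume changes to
    ``a b c sqrt(1 - cos^2 a - cos^2 b - cos^2 g + 2 cos a cos b cos g)``.
    """
    return vectors_from_parameters(
        CellParameters(*lengths, target.alpha, target.beta, target.gamma)
    )


def parameters_from_vectors(vectors: np.ndarray) -> CellParameters:
    v = np.asarray(vectors, dtype=float)
    lengths = np.linalg.norm(v, axis=1)

    def angle(i: int, j: int) -> float:
        cosang = float(v[i] @ v[j] / (lengths[i] * lengths[j]))
        return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))

    return CellParameters(
        float(lengths[0]),
        float(lengths[1]),
        float(lengths[2]),
        angle(1, 2),
        angle(0, 2),
        angle(0, 1),
    )


def cell_volume(vectors: np.ndarray) -> float:
    return float(abs(np.linalg.det(np.asarray(vectors, dtype=float))))
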