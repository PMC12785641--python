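"""Space group P-1 (and P1), special positions and minimum-image distances.

Only the triclinic groups are first class here: P1 (identity) and P-1
(identity plus inversion through the origin).  The operator-list
representation is generic, so other groups could be added, but nothing in
the generator requires them.

Special positions
-----------------
P-1 has eight inversion centers (all 0/1/2-halves combinations).  The
default group ships FOUR of them — (0,0,0), (1/2,0,0), (0,1/2,0),
(0,0,1/2) — matching the four-position occupancy model whose statistics
(81.4% / 17.2% / 1.4% of structures with zero / one / more than one
occupied center at p = 0.05) the generator reproduces.  The full
eight-center variant is available via :func:`p1bar_group`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "SpaceGroup",
    "SiteKind",
    "p1_group",
    "p1bar_group",
    "sample_special_occupancy",
    "expand_to_unit_cell",
    "min_image_distance",
    "min_cell_height",
    "shift_table",
]

GENERAL = "general"
SPECIAL = "special"


@dataclass(frozen=True)
class SiteKind:
    kind: str = GENERAL
    position_index: int | None = None


@dataclass(frozen=True)
class SpaceGroup:
    """Operator list (rotation matrix, translation) plus special positions."""

    name: str
    operators: tuple = ()
    special_positions: tuple = ()

    @property
    def n_ops(self) -> int:
        return len(self.operators)

    def operator_strings(self) -> list[str]:
        """CIF-style xyz operator strings."""
        out = []
        axes = "xyz"
        for rot, trans in self.operators:
            parts = []
            for i in range(3):
                term = ""
                for j in range(3):
                    r = rot[i][j]
                    if r == 1:
                        term += ("+" if term else "") + axes[j]
                    elif r == -1:
                        term += "-" + axes[j]
                    elif r != 0:
                        raise ConfigurationError("non-unimodular operator")
                t = trans[i]
                if abs(t) > 1e-9:
                    term += f"+{t:g}" if t > 0 else f"{t:g}"
                parts.append(term)
            out.append(",".join(parts))
        return out


_IDENTITY = (np.eye(3, dtype=int), np.zeros(3))
_INVERSION = (-np.eye(3, dtype=int), np.zeros(3))

_FOUR_CENTERS = (
    (0.0, 0.0, 0.0),
    (0.5, 0.0, 0.0),
    (0.0, 0.5, 0.0),
    (0.0, 0.0, 0.5),
)
_EIGHT_CENTERS = tuple(
    (0.5 * i, 0.5 * j, 0.5 * k) for i in (0, 1) for j in (0, 1) for k in (0, 1)
)


def p1_group() -> SpaceGroup:
    return SpaceGroup("P1", operators=(_IDENTITY,), special_positions=())


def p1bar_group(n_special: int = 4) -> SpaceGroup:
    """P-1 with the 4-center default or the full 8-center set."""
    if n_special == 4:
        centers = _FOUR_CENTERS
    elif n_special == 8:
        centers = _EIGHT_CENTERS
    else:
        raise ConfigurationError(f"n_special must be 4 or 8, got {n_special}")
    return SpaceGroup(
        "P-1",
        operators=(_IDENTITY, _INVERSION),
        special_positions=tuple(np.asarray(c) for c in centers),
    )


def sample_special_occupancy(
    p: float, group: SpaceGroup, rng: np.random.Generator
) -> list[int]:
    """Each listed special position occupied independently with probability p."""
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"probability must be in [0, 1], got {p}")
    n = len(group.special_positions)
    if n == 0:
        return []
    return [int(i) for i in np.flatnonzero(rng.random(n) < p)]


def _wrap(frac: np.ndarray) -> np.ndarray:
    out = frac - np.floor(frac)
    # values that round up to exactly 1.0 belong at 0.0
    out[out >= 1.0] = 0.0
    return out


def expand_to_unit_cell(
    asym_frac: np.ndarray, group: SpaceGroup, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Apply every operator to every asymmetric-unit site.

    Returns ``(frac, parent)`` where ``frac`` holds wrapped fractional
    coordinates of all distinct images and ``parent[i]`` is the index of
    the generating asymmetric atom.  Images coinciding within ``tol``
    (periodically) collapse to one — special positions keep multiplicity 1.
    """
    asym_frac = np.atleast_2d(np.asarray(asym_frac, dtype=float))
    coords: list[np.ndarray] = []
    parents: list[int] = []
    for idx, x in enumerate(asym_frac):
        seen: list[np.ndarray] = []
        for rot, trans in group.operators:
            img = _wrap(np.asarray(rot, dtype=float) @ x + trans)
            dup = False
            for s in seen:
                d = img - s
                d -= np.round(d)
                if np.max(np.abs(d)) < tol:
                    dup = True
                    break
            if not dup:
                seen.append(img)
        coords.extend(seen)
        parents.extend([idx] * len(seen))
    if not coords:
        return np.empty((0, 3)), np.empty(0, dtype=int)
    return np.asarray(coords), np.asarray(parents, dtype=int)


def shift_table(n: int = 1) -> np.ndarray:
    """All integer translations with components in [-n, n]."""
    r = np.arange(-n, n + 1)
    return np.stack(np.meshgrid(r, r, r, indexing="ij"), axis=-1).reshape(-1, 3)


def min_cell_height(vectors: np.ndarray) -> float:
    """Shortest perpendicular distance between opposite cell faces."""
    v = np.asarray(vectors, dtype=float)
    vol = abs(np.linalg.det(v))
    heights = [
        vol / np.linalg.norm(np.cross(v[(i + 1) % 3], v[(i + 2) % 3])) for i in range(3)
    ]
    return float(min(heights))


def min_image_distance(
    x1, x2, vectors: np.ndarray, n_shift: int | None = None
) -> float:
    """Minimum Cartesian distance between periodic images of two sites.

    Scans the ``(2n+1)^3`` translations of ``x2``; by default ``n`` starts
    at 1 and expands automatically until the result is provably minimal
    (the found distance is below ``(n - 1/2)`` times the shortest cell
    height, so no image outside the scanned block can beat it).
    """
    v = np.asarray(vectors, dtype=float)
    delta = np.asarray(x2, dtype=float) - np.asarray(x1, dtype=float)
    delta -= np.round(delta)  # principal image first; shifts cover the rest
    h = min_cell_height(v)
    n = 1 if n_shift is None else n_shift
    while True:
        cart = (delta + shift_table(n)) @ v
        d = float(np.sqrt(np.min(np.sum(cart * cart, axis=1))))
        if n_shift is not None or d <= (n - 0.5) * h or n >= 4:
            return d
        n += 1
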