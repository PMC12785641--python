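"""Filling a unit cell with atoms.

Two placement strategies populate the asymmetric unit of a (possibly
skewed) cell:

* ``place_uniform`` — fully random fractional coordinates accepted by
  rejection sampling against a single minimum-contact distance;
* ``grow_artificial_molecule`` — cluster growth: each new atom is placed
  on a sphere of bonding radius around a randomly chosen existing atom,
  and every interatomic distance must either fall inside the covalent
  bond window or stay beyond a non-bonded floor, producing molecule-like
  distance statistics without any chemical valence rules.

Both honour periodic boundary conditions (neighbouring cells included in
every distance check), symmetry images of already-placed atoms, and the
candidate's own inversion image.  Contacts between an atom and its own
pure lattice translations are a property of the cell, not of the atom,
and are excluded.

Atom counts come from a content budget derived from the cell volume: an
average volume per non-hydrogen atom and a hydrogen mole fraction, both
sampled uniformly from database-calibrated ranges.
"""
from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DomainError
from .oblique import CellParameters, parameters_from_vectors
from .symmetry import (
    GENERAL,
    SPECIAL,
    SiteKind,
    SpaceGroup,
    min_cell_height,
    shift_table,
)

__all__ = [
    "ContentBudget",
    "PlacementRules",
    "ElementFrequencyTable",
    "Atom",
    "CrystalStructure",
    "PlacementReport",
    "ShortfallWarning",
    "sample_budget",
    "populate_special_positions",
    "place_uniform",
    "grow_artificial_molecule",
    "sample_sphere_point",
    "assign_adps",
    "make_equal_atom",
]


class ShortfallWarning(UserWarning):
    """Fewer atoms placed than budgeted (retry exhaustion)."""


@dataclass(frozen=True)
class ContentBudget:
    """Target atom counts for one asymmetric unit."""

    v_atom: float
    x_h: float
    n_nonh: int
    n_h: int

    def __post_init__(self) -> None:
        if not self.v_atom > 0:
            raise ConfigurationError(f"v_atom must be > 0, got {self.v_atom}")
        if not 0.0 <= self.x_h < 1.0:
            raise ConfigurationError(f"x_h must be in [0, 1), got {self.x_h}")
        if self.n_nonh < 1:
            raise ConfigurationError(f"n_nonh must be >= 1, got {self.n_nonh}")


@dataclass(frozen=True)
class PlacementRules:
    """Contact thresholds and retry limits for both placement modes."""

    d_min_contact: float = 1.2
    bond_window: tuple[float, float] = (0.9, 1.1)
    nonbond_factor: float = 1.5
    max_coord_retries: int = 10
    max_growth_retries: int = 20

    def __post_init__(self) -> None:
        low, high = self.bond_window
        if not 0 < low < high:
            raise ConfigurationError(f"need 0 < low < high, got {self.bond_window}")
        if not self.nonbond_factor > high:
            raise ConfigurationError(
                f"nonbond_factor ({self.nonbond_factor}) must exceed the upper "
                f"bond-window factor ({high})"
            )
        if self.max_coord_retries < 1 or self.max_growth_retries < 1:
            raise ConfigurationError("retry limits must be >= 1")


def _read_two_column(path) -> dict[str, float]:
    out: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        sym, val = line.split()
        out[sym] = float(val)
    return out


def _data_path(name: str) -> Path:
    return Path(str(resources.files("xtalgen").joinpath("data", name)))


@dataclass(frozen=True)
class ElementFrequencyTable:
    """Discrete element distributions for general and special positions,
    plus covalent radii.

    Hydrogen is deliberately absent from both frequency tables: hydrogen
    counts are budgeted separately and the skeletal growth pool excludes
    hydrogen.
    """

    general: dict[str, float]
    special: dict[str, float]
    radii: dict[str, float]

    def __post_init__(self) -> None:
        for name, table in (("general", self.general), ("special", self.special)):
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"{name} element frequencies sum to {total!r}, not 1"
                )
            if "H" in table:
                raise ConfigurationError(
                    f"hydrogen may not appear in the {name} frequency table"
                )
            missing = [el for el in table if el not in self.radii]
            if missing:
                raise ConfigurationError(f"no covalent radius for {missing}")
        if "H" not in self.radii:
            raise ConfigurationError("covalent radius table must include H")

    @classmethod
    def default(cls) -> "ElementFrequencyTable":
        return cls.from_files(
            _data_path("element_freq_general.tsv"),
            _data_path("element_freq_special.tsv"),
            _data_path("covalent_radii.tsv"),
        )

    @classmethod
    def from_files(cls, general_path, special_path, radii_path) -> "ElementFrequencyTable":
        return cls(
            general=_read_two_column(general_path),
            special=_read_two_column(special_path),
            radii=_read_two_column(radii_path),
        )

    def draw(self, which: str, rng: np.random.Generator) -> str:
        table = self.general if which == GENERAL else self.special
        elements = list(table)
        probs = np.asarray(list(table.values()))
        return str(rng.choice(elements, p=probs / probs.sum()))

    def radius(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            raise ConfigurationError(f"no covalent radius for element {element!r}")


@dataclass
class Atom:
    element: str
    frac: np.ndarray
    u_iso: float = 0.03
    site: SiteKind = field(default_factory=SiteKind)

    def __post_init__(self) -> None:
        self.frac = np.asarray(self.frac, dtype=float)


@dataclass
class PlacementReport:
    requested_nonh: int = 0
    placed_nonh: int = 0
    requested_h: int = 0
    placed_h: int = 0
    seconds: float = 0.0

    @property
    def shortfall(self) -> int:
        return (self.requested_nonh - self.placed_nonh) + (
            self.requested_h - self.placed_h
        )


@dataclass
class CrystalStructure:
    """Unit cell, space group and asymmetric-unit atom list."""

    parameters: CellParameters
    vectors: np.ndarray
    group: SpaceGroup
    atoms: list[Atom] = field(default_factory=list)
    report: PlacementReport | None = None

    @classmethod
    def from_vectors(cls, vectors: np.ndarray, group: SpaceGroup) -> "CrystalStructure":
        return cls(parameters_from_vectors(vectors), np.asarray(vectors, float), group)

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.vectors)))

    def n_nonh(self) -> int:
        return sum(1 for a in self.atoms if a.element != "H")


def sample_budget(
    volume: float,
    group: SpaceGroup,
    rng: np.random.Generator,
    v_atom_range: tuple[float, float] = (7.0, 22.0),
    x_h_range: tuple[float, float] = (0.3, 0.6),
) -> ContentBudget:
    """Draw the content budget for one structure.

    ``n_nonh = round(V / (n_ops * v_atom))`` floored at 1, with
    ``v_atom ~ U(v_atom_range)``; then ``n_h = round(n_nonh * x/(1-x))``
    with the hydrogen mole fraction ``x ~ U(x_h_range)``.
    """
    if not volume > 0:
        raise DomainError(f"volume must be > 0, got {volume}")
    v_atom = float(rng.uniform(*v_atom_range))
    n_nonh = max(int(round(volume / (group.n_ops * v_atom))), 1)
    x_h = float(rng.uniform(*x_h_range))
    n_h = int(round(n_nonh * x_h / (1.0 - x_h)))
    return ContentBudget(v_atom=v_atom, x_h=x_h, n_nonh=n_nonh, n_h=n_h)


def sample_sphere_point(
    center: np.ndarray, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform point on the sphere of given radius (normalized-Gaussian method)."""
    if not radius > 0:
        raise DomainError(f"radius must be > 0, got {radius}")
    while True:
        g = rng.standard_normal(3)
        norm = np.linalg.norm(g)
        if norm > 1e-12:
            return np.asarray(center, dtype=float) + radius * g / norm


def _wrap(frac: np.ndarray) -> np.ndarray:
    out = frac - np.floor(frac)
    out[out >= 1.0] = 0.0
    return out


class _ClashChecker:
    """Incremental periodic clash checks against expanded symmetry images.

    Keeps the expanded (full-cell) image coordinates and radii of every
    placed atom; candidate checks are vectorized over all images and all
    lattice translations within the scan block.  The block size is chosen
    from the largest active contact threshold and the shortest cell
    height, so no violating image can hide outside it.
    """

    def __init__(self, vectors: np.ndarray, group: SpaceGroup, max_threshold: float):
        self.vectors = np.asarray(vectors, dtype=float)
        self.group = group
        h = min_cell_height(self.vectors)
        self.n_shift = max(1, math.ceil(max_threshold / h))
        self.shifts = shift_table(self.n_shift).astype(float)
        self._frac = np.empty((0, 3))
        self._radii = np.empty(0)

    def images_of(self, frac: np.ndarray, special: bool) -> np.ndarray:
        if special:
            return _wrap(np.asarray(frac, float))[None, :]
        imgs = []
        for rot, trans in self.group.operators:
            imgs.append(_wrap(np.asarray(rot, float) @ frac + trans))
        return np.asarray(imgs)

    def add(self, frac: np.ndarray, radius: float, special: bool) -> None:
        imgs = self.images_of(frac, special)
        self._frac = np.vstack([self._frac, imgs])
        self._radii = np.concatenate([self._radii, np.full(len(imgs), radius)])

    def _distances(self, cand: np.ndarray, targets: np.ndarray) -> np.ndarray:
        """(n_targets, n_shifts) Cartesian distances to all translated images."""
        delta = targets - cand
        delta -= np.round(delta)
        cart = (delta[:, None, :] + self.shifts[None, :, :]) @ self.vectors
        return np.sqrt(np.sum(cart * cart, axis=2))

    def _self_images(self, cand: np.ndarray, special: bool) -> np.ndarray:
        """Non-identity symmetry images of the candidate itself."""
        if special or self.group.n_ops == 1:
            return np.empty((0, 3))
        return self.images_of(cand, special=False)[1:]

    def ok_uniform(self, cand: np.ndarray, d_min: float, special: bool = False) -> bool:
        targets = np.vstack([self._frac, self._self_images(cand, special)])
        if len(targets) == 0:
            return True
        d = self._distances(cand, targets)
        return bool(np.min(d) >= d_min)

    def ok_molecule(
        self,
        cand: np.ndarray,
        radius: float,
        low: float,
        high: float,
        nonbond: float,
        special: bool = False,
    ) -> bool:
        self_imgs = self._self_images(cand, special)
        targets = np.vstack([self._frac, self_imgs])
        if len(targets) == 0:
            return True
        rsum = np.concatenate([self._radii, np.full(len(self_imgs), radius)]) + radius
        d = self._distances(cand, targets)
        lo = low * rsum[:, None]
        hi = high * rsum[:, None]
        floor = nonbond * rsum[:, None]
        bad = (d < lo) | ((d > hi) & (d < floor))
        return not bool(np.any(bad))


def _max_threshold(rules: PlacementRules, table: ElementFrequencyTable, mode: str) -> float:
    if mode == "uniform":
        return rules.d_min_contact
    rmax = max(table.radii.values())
    return rules.nonbond_factor * 2.0 * rmax


def populate_special_positions(
    structure: CrystalStructure,
    occupied: list[int],
    table: ElementFrequencyTable,
    rng: np.random.Generator,
    rules: PlacementRules | None = None,
    mode: str = "molecules",
) -> CrystalStructure:
    """Put one atom (element from the special-position table) on each
    occupied inversion center.

    When ``rules`` are given, the active contact rule is enforced between
    special positions too (their geometry is fixed, so only the element —
    via its covalent radius — can be re-drawn, up to the growth retry
    limit; an unsatisfiable center is left empty).
    """
    checker = (
        _ClashChecker(structure.vectors, structure.group, _max_threshold(rules, table, mode))
        if rules is not None
        else None
    )
    for idx in occupied:
        pos = np.asarray(structure.group.special_positions[idx], dtype=float)
        element = table.draw(SPECIAL, rng)
        if checker is not None:
            ok = False
            for _ in range(rules.max_growth_retries):
                if mode == "uniform":
                    ok = checker.ok_uniform(pos, rules.d_min_contact, special=True)
                else:
                    low, high = rules.bond_window
                    ok = checker.ok_molecule(
                        pos, table.radius(element), low, high,
                        rules.nonbond_factor, special=True,
                    )
                if ok:
                    break
                element = table.draw(SPECIAL, rng)
            if not ok:
                continue  # fixed geometry admits no element: leave center empty
            checker.add(pos, table.radius(element), special=True)
        structure.atoms.append(
            Atom(element=element, frac=pos, site=SiteKind(SPECIAL, idx))
        )
    return structure


def _new_checker(
    structure: CrystalStructure,
    rules: PlacementRules,
    table: ElementFrequencyTable,
    mode: str,
) -> _ClashChecker:
    checker = _ClashChecker(
        structure.vectors, structure.group, _max_threshold(rules, table, mode)
    )
    for atom in structure.atoms:
        checker.add(
            atom.frac, table.radius(atom.element), atom.site.kind == SPECIAL
        )
    return checker


def place_uniform(
    structure: CrystalStructure,
    budget: ContentBudget,
    rules: PlacementRules,
    table: ElementFrequencyTable,
    rng: np.random.Generator,
) -> CrystalStructure:
    """Rejection-sampled uniform placement.

    Non-hydrogen atoms first, then hydrogens; every candidate must keep a
    minimum-image distance of at least ``d_min_contact`` from every image
    of every atom already present (including its own inversion image).
    Candidates failing ``max_coord_retries`` coordinate draws are
    discarded; the shortfall is recorded on the report and warned about.
    """
    t0 = time.perf_counter()
    checker = _new_checker(structure, rules, table, "uniform")
    n_special = len(structure.atoms)
    n_general = max(budget.n_nonh - n_special, 0)
    report = PlacementReport(requested_nonh=n_general, requested_h=budget.n_h)

    def try_place(element: str) -> bool:
        for _ in range(rules.max_coord_retries):
            cand = rng.random(3)
            if checker.ok_uniform(cand, rules.d_min_contact):
                checker.add(cand, table.radius(element), special=False)
                structure.atoms.append(Atom(element=element, frac=cand))
                return True
        return False

    for _ in range(n_general):
        if try_place(table.draw(GENERAL, rng)):
            report.placed_nonh += 1
    for _ in range(budget.n_h):
        if try_place("H"):
            report.placed_h += 1

    report.seconds = time.perf_counter() - t0
    structure.report = report
    if report.shortfall:
        warnings.warn(
            f"placed {report.placed_nonh}/{report.requested_nonh} non-H and "
            f"{report.placed_h}/{report.requested_h} H atoms (retry exhaustion)",
            ShortfallWarning,
            stacklevel=2,
        )
    return structure


def grow_artificial_molecule(
    structure: CrystalStructure,
    budget: ContentBudget,
    rules: PlacementRules,
    table: ElementFrequencyTable,
    rng: np.random.Generator,
) -> CrystalStructure:
    """Cluster growth producing molecule-like interatomic distances.

    A seed atom is placed uniformly; every further atom bonds to a
    randomly selected existing atom at a distance drawn uniformly from the
    covalent bond window of the pair, in a direction uniform on the
    sphere.  All distances to every image must fall either inside the
    bond window of the pair or beyond the non-bonded floor.  The retry
    ladder per atom: ``max_growth_retries`` attempts, then one element
    re-draw with the same number of attempts, then the atom is discarded.
    The non-hydrogen skeleton is completed before any hydrogen is
    attached; hydrogens bond only to non-hydrogen parents.
    """
    t0 = time.perf_counter()
    checker = _new_checker(structure, rules, table, "molecules")
    low, high = rules.bond_window
    nonbond = rules.nonbond_factor
    inv_vectors = np.linalg.inv(structure.vectors)

    n_special = len(structure.atoms)
    n_general = max(budget.n_nonh - n_special, 0)
    report = PlacementReport(requested_nonh=n_general, requested_h=budget.n_h)

    def accept(cand: np.ndarray, element: str) -> bool:
        if checker.ok_molecule(cand, table.radius(element), low, high, nonbond):
            checker.add(cand, table.radius(element), special=False)
            structure.atoms.append(Atom(element=element, frac=cand))
            return True
        return False

    def place_seed(element: str) -> bool:
        for _ in range(rules.max_growth_retries):
            if accept(rng.random(3), element):
                return True
        return False

    def grow_one(element: str, parents: list[Atom]) -> bool:
        r_new = table.radius(element)
        for _ in range(rules.max_growth_retries):
            parent = parents[rng.integers(len(parents))]
            r_sum = table.radius(parent.element) + r_new
            bond = rng.uniform(low * r_sum, high * r_sum)
            center = parent.frac @ structure.vectors
            cand = _wrap(sample_sphere_point(center, bond, rng) @ inv_vectors)
            if accept(cand, element):
                return True
        return False

    for k in range(n_general):
        parents = list(structure.atoms)
        # the first general atom is the seed Z, uniform in the cell (also
        # the fallback whenever nothing has been placed yet)
        if k == 0 or not parents:
            if place_seed(table.draw(GENERAL, rng)):
                report.placed_nonh += 1
            continue
        element = table.draw(GENERAL, rng)
        if grow_one(element, parents):
            report.placed_nonh += 1
        elif grow_one(table.draw(GENERAL, rng), parents):  # element re-draw rung
            report.placed_nonh += 1
        # else: discard atom

    heavy = [a for a in structure.atoms if a.element != "H"]
    for _ in range(budget.n_h):
        if heavy and grow_one("H", heavy):
            report.placed_h += 1

    report.seconds = time.perf_counter() - t0
    structure.report = report
    if report.shortfall:
        warnings.warn(
            f"placed {report.placed_nonh}/{report.requested_nonh} non-H and "
            f"{report.placed_h}/{report.requested_h} H atoms (retry exhaustion)",
            ShortfallWarning,
            stacklevel=2,
        )
    return structure


def assign_adps(
    atoms: list[Atom],
    rng: np.random.Generator,
    u_range: tuple[float, float] = (0.01, 0.1),
    dev_range: tuple[float, float] = (-0.005, 0.005),
    u_floor: float = 0.001,
) -> list[Atom]:
    """One structure-level isotropic U plus an individual deviation per atom,
    clamped below at ``u_floor``."""
    u_struct = float(rng.uniform(*u_range))
    for atom in atoms:
        atom.u_iso = max(u_struct + float(rng.uniform(*dev_range)), u_floor)
    return atoms


def make_equal_atom(structure: CrystalStructure, element: str = "C") -> CrystalStructure:
    """Replace every element by a single one; geometry untouched. Idempotent."""
    for atom in structure.atoms:
        atom.element = element
    return structure
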