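"""End-to-end structure generation.

``generate_structure(config, k)`` builds structure ``k`` of a batch from
its own seeded substream, so any structure is reproducible independently
of batch size; ``generate_batch`` lazily yields ``(structure,
reflections)`` pairs with O(1) memory.

Pipeline per structure: sample a feasible volume -> derive bounded cell
lengths -> random permutation -> orthorhombic embedding -> optional
monoclinic/triclinic skew -> special-position occupancy -> content budget
-> atom placement (uniform / artificial molecules / equal atoms) -> ADPs
-> reflection list, structure factors, completeness.
"""
from __future__ import annotations

import math
from functools import lru_cache
from typing import Iterator

import numpy as np

from .cells import CellLengths, cell_from_volume, permute_lengths, sample_volume_feasible
from .config import GeneratorConfig
from .diffraction import (
    FormFactorTable,
    ReflectionSet,
    apply_completeness,
    reflection_list,
    structure_factors,
)
from .oblique import (
    CellParameters,
    apply_length_preserving,
    parameters_from_vectors,
    sample_skew_t,
    skew_monoclinic,
    skew_triclinic,
    vectors_from_lengths,
)
from .placement import (
    CrystalStructure,
    ElementFrequencyTable,
    assign_adps,
    grow_artificial_molecule,
    make_equal_atom,
    place_uniform,
    populate_special_positions,
    sample_budget,
)
from .rng import structure_rng
from .symmetry import p1_group, p1bar_group, sample_special_occupancy

__all__ = ["generate_structure", "generate_batch", "element_table_for"]


@lru_cache(maxsize=8)
def _cached_default_table() -> ElementFrequencyTable:
    return ElementFrequencyTable.default()


@lru_cache(maxsize=8)
def _cached_form_factors() -> FormFactorTable:
    return FormFactorTable.default()


def element_table_for(config: GeneratorConfig) -> ElementFrequencyTable:
    if config.general_table or config.special_table or config.radii_table:
        default = _cached_default_table()
        from .placement import _read_two_column

        return ElementFrequencyTable(
            general=_read_two_column(config.general_table)
            if config.general_table
            else default.general,
            special=_read_two_column(config.special_table)
            if config.special_table
            else default.special,
            radii=_read_two_column(config.radii_table)
            if config.radii_table
            else default.radii,
        )
    return _cached_default_table()


def _skewed_vectors(
    config: GeneratorConfig, lengths: CellLengths, rng: np.random.Generator
) -> np.ndarray:
    vectors = vectors_from_lengths(lengths)
    skew = config.skew
    if skew.lattice_kind == "orthorhombic":
        return vectors
    b_len = float(lengths[1])
    c_len = float(lengths[2])
    if skew.lattice_kind == "monoclinic":
        t = sample_skew_t(skew, c_len, config.bounds, rng)
        sheared = skew_monoclinic(vectors, t)
    else:
        t_ab = sample_skew_t(skew, b_len, config.bounds, rng)
        t_ac = sample_skew_t(skew, c_len, config.bounds, rng)
        # remaining headroom after the first c-shear
        t_bc = sample_skew_t(skew, c_len * math.sqrt(1 + t_ac**2), config.bounds, rng)
        sheared = skew_triclinic(vectors, t_ab, t_ac, t_bc)
    if skew.length_preserving:
        angles = parameters_from_vectors(sheared)
        return apply_length_preserving(lengths, angles)
    return sheared


def generate_structure(
    config: GeneratorConfig, index: int, with_diffraction: bool = True
) -> tuple[CrystalStructure, ReflectionSet | None]:
    """Build structure ``index`` and its reflection data from scratch.

    ``with_diffraction=False`` skips the structure-factor computation and
    returns ``None`` for the reflection set (useful for placement-only
    ensembles).
    """
    rng = structure_rng(config.seed, index)
    table = element_table_for(config)
    form_factors = _cached_form_factors()

    volume = sample_volume_feasible(config.volume, config.bounds, rng)
    lengths = permute_lengths(cell_from_volume(volume, config.bounds, rng), rng)
    vectors = _skewed_vectors(config, lengths, rng)

    group = (
        p1bar_group(config.n_special_positions)
        if config.space_group == "P-1"
        else p1_group()
    )
    structure = CrystalStructure.from_vectors(vectors, group)

    occupied = sample_special_occupancy(config.special_p, group, rng)
    mode = "uniform" if config.placement_mode in ("uniform", "equal_atoms") else "molecules"
    populate_special_positions(structure, occupied, table, rng, config.rules, mode)

    budget = sample_budget(
        structure.volume, group, rng, config.v_atom_range, config.x_h_range
    )
    if config.placement_mode == "molecules":
        grow_artificial_molecule(structure, budget, config.rules, table, rng)
    else:
        place_uniform(structure, budget, config.rules, table, rng)
        if config.placement_mode == "equal_atoms":
            make_equal_atom(structure, config.equal_atom_element)

    assign_adps(structure.atoms, rng, config.u_range, config.dev_range)

    if not with_diffraction:
        return structure, None
    dconf = config.diffraction.drawn(rng)
    refs = reflection_list(vectors, dconf)
    refs = structure_factors(structure, refs, form_factors)
    refs = apply_completeness(refs, dconf, rng)
    return structure, refs


def generate_batch(
    config: GeneratorConfig, n: int, start: int = 0
) -> Iterator[tuple[CrystalStructure, ReflectionSet]]:
    """Lazily yield ``n`` structures beginning at index ``start``."""
    for k in range(start, start + n):
        try:
            yield generate_structure(config, k)
        except Exception as exc:
            raise type(exc)(f"structure {k}: {exc}") from exc
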