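"""Shared fixtures and independent brute-force oracles.

The distance-audit oracle here deliberately shares no code with the
placement path: it expands symmetry images by explicit operator loops,
builds an absolute supercell and measures all pair distances with
``scipy.spatial.distance.cdist``.
"""
from __future__ import annotations

import warnings

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from xtalgen.config import GeneratorConfig
from xtalgen.pipeline import generate_structure
from xtalgen.placement import ElementFrequencyTable, ShortfallWarning


@pytest.fixture(scope="session")
def freq_table() -> ElementFrequencyTable:
    return ElementFrequencyTable.default()


def brute_force_pair_distances(structure, n_super: int = 2):
    """All (distance, image_i, image_j, element_i, element_j) over a
    (2n+1)^3 supercell, excluding pure translations of the same image.

    Returns (distances array of shape (n_pairs,), rsum-lookup inputs):
    arrays ``d``, ``ei``, ``ej`` where elements are atom symbols.
    """
    ops = [(np.asarray(r, dtype=float), np.asarray(t, dtype=float))
           for r, t in structure.group.operators]
    images = []
    elements = []
    for atom in structure.atoms:
        seen = []
        for rot, trans in ops:
            img = rot @ atom.frac + trans
            img = img % 1.0
            if any(np.max(np.abs((img - s) - np.round(img - s))) < 1e-6 for s in seen):
                continue
            seen.append(img)
        images.extend(seen)
        elements.extend([atom.element] * len(seen))
    images = np.asarray(images)
    n = len(images)
    if n < 2 and structure.group.n_ops == 1:
        return np.empty(0), [], []

    cell = np.asarray(structure.vectors, dtype=float)
    rng_shift = range(-n_super, n_super + 1)
    shifts = np.array([[i, j, k] for i in rng_shift for j in rng_shift for k in rng_shift],
                      dtype=float)
    super_frac = (shifts[:, None, :] + images[None, :, :]).reshape(-1, 3)
    super_img_idx = np.tile(np.arange(n), len(shifts))
    central = images @ cell
    super_cart = super_frac @ cell

    d_matrix = cdist(central, super_cart)
    row_idx = np.repeat(np.arange(n), d_matrix.shape[1]).reshape(d_matrix.shape)
    col_img = np.broadcast_to(super_img_idx, d_matrix.shape)
    keep = row_idx < col_img  # one orientation per image pair; drops self-translations
    d = d_matrix[keep]
    ei = [elements[i] for i in row_idx[keep]]
    ej = [elements[j] for j in col_img[keep]]
    return d, ei, ej


def audit_uniform(structure, d_min: float, n_super: int = 2) -> int:
    """Number of pair distances below d_min (0 expected)."""
    d, _, _ = brute_force_pair_distances(structure, n_super)
    return int(np.sum(d < d_min * (1 - 1e-9)))


def audit_molecule(structure, table, low, high, nonbond, n_super: int = 2) -> int:
    """Number of pairs violating the bond-window-or-nonbond-floor dichotomy."""
    d, ei, ej = brute_force_pair_distances(structure, n_super)
    if len(d) == 0:
        return 0
    rsum = np.array([table.radius(a) + table.radius(b) for a, b in zip(ei, ej)])
    eps = 1e-9
    bad = (d < low * rsum * (1 - eps)) | (
        (d > high * rsum * (1 + eps)) & (d < nonbond * rsum * (1 - eps))
    )
    return int(np.sum(bad))


def make_structures(mode: str, n: int, seed: int, **config_kwargs):
    cfg = GeneratorConfig(seed=seed, placement_mode=mode, **config_kwargs)
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ShortfallWarning)
        for k in range(n):
            out.append(generate_structure(cfg, k, with_diffraction=False)[0])
    return out


@pytest.fixture(scope="session")
def molecule_structures():
    """Medium ensemble for placement/diffraction properties."""
    return make_structures("molecules", 120, seed=11)


@pytest.fixture(scope="session")
def uniform_structures():
    return make_structures("uniform", 120, seed=12)
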